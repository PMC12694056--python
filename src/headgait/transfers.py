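"""Sit-to-stand / stand-to-sit transfer detection from vertical head position.

Frames are clustered into sitting and standing postures (two-cluster k-means
on z); each contiguous standing run is bracketed by the transfers that lead
into and out of it.  Transfer boundaries are the nearest frames where the
absolute vertical speed drops below a stillness threshold (0.001 m/s):
sit-to-stand runs from the last still frame before the standing run to the
first still frame inside it; stand-to-sit mirrors this at the run's end.
Transfers truncated by the recording boundaries are discarded (their duration
would be censored).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cluster import kmeans_two
from .segments import MetricsRecord
from .squats import _boundary_velocity


@dataclass
class TransferSegment:
    start: int
    end: int
    kind: str        # "sit_to_stand" | "stand_to_sit"
    duration: float  # s


def detect_transfers(z: np.ndarray, rate: float, seed: int = 0, *,
                     speed_threshold: float = 0.001,
                     min_centroid_gap: float = 0.1,
                     kmeans_iters: int = 10,
                     vel_window: int = 5) -> list[TransferSegment]:
    z = np.asarray(z, dtype=float)
    n = len(z)
    labels, centers = kmeans_two(z, iters=kmeans_iters, seed=seed)
    if labels is None or centers[1] - centers[0] < min_centroid_gap:
        return []  # unimodal vertical position: no posture change
    standing = labels == 1
    vel = _boundary_velocity(z, rate, vel_window)
    still = np.abs(vel) < speed_threshold

    transfers: list[TransferSegment] = []
    i = 0
    while i < n:
        if not standing[i]:
            i += 1
            continue
        s = i
        while i < n and standing[i]:
            i += 1
        e = i  # standing run [s, e)
        # sit-to-stand: last still frame before the run -> first still inside
        a = s - 1
        while a >= 0 and not still[a]:
            a -= 1
        b = s
        while b < e and not still[b]:
            b += 1
        if a >= 0 and b < e and b > a:
            transfers.append(TransferSegment(a, b, "sit_to_stand", (b - a) / rate))
        # stand-to-sit: last still frame inside the run -> first still after
        c = e - 1
        while c >= s and not still[c]:
            c -= 1
        d = e
        while d < n and not still[d]:
            d += 1
        if c >= s and d < n and d > c:
            transfers.append(TransferSegment(c, d, "stand_to_sit", (d - c) / rate))
    return transfers


def transfer_metrics(transfers: list[TransferSegment]) -> MetricsRecord | None:
    """Per-trial mean transfer duration per kind; a kind without events is
    simply absent from the values."""
    if not transfers:
        return None
    values = {}
    for kind in ("sit_to_stand", "stand_to_sit"):
        durs = [t.duration for t in transfers if t.kind == kind]
        if durs:
            values[f"{kind}_duration_s"] = float(np.mean(durs))
    return MetricsRecord(source="", state="transfers", values=values,
                         n_segments=len(transfers))
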