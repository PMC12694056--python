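"""Squat detection from the vertical head position.

Local minima of z are clustered (two-cluster k-means on the minimum values)
into deep valleys (squats) versus shallow dips (bending forward, minor
postural drops).  Each squat valley is then bounded by the nearest
zero-crossings of the vertical velocity on either side; squat depth is the
drop from the baseline (mean of the start/end positions) to the valley.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .cluster import kmeans_two
from .segments import MetricsRecord


@dataclass
class SquatSegment:
    start: int
    end: int           # half-open; duration = (end - start) / rate
    valley: int        # frame of minimum z
    duration: float    # s
    depth: float       # m


def _boundary_velocity(z: np.ndarray, rate: float, window: int) -> np.ndarray:
    # short-window SG derivative: keeps movement tails below the stillness
    # threshold tight around the true movement interval
    window = min(window if window % 2 else window + 1, len(z) - (1 - len(z) % 2))
    return savgol_filter(z, window, 2, deriv=1, delta=1.0 / rate, mode="interp")


def detect_squats(z: np.ndarray, rate: float, seed: int = 0, *,
                  prominence: float = 0.02, min_dist_s: float = 1.0,
                  group_window_s: float = 8.0, kmeans_iters: int = 10,
                  vel_tol: float = 0.001, vel_window: int = 5) -> list[SquatSegment]:
    """Detect squats in a smoothed vertical head-position channel.

    Requires at least two local minima (otherwise no squats are reported);
    degenerate clustering (all minima at one value) also yields no squats.
    Valleys closer than ``group_window_s`` are treated as one burst of
    consecutive squats, but each valley still receives its own boundaries.
    """
    z = np.asarray(z, dtype=float)
    n = len(z)
    minima, _ = find_peaks(-z, prominence=prominence,
                           distance=max(1, int(round(min_dist_s * rate))))
    if len(minima) < 2:
        return []
    labels, centers = kmeans_two(z[minima], iters=kmeans_iters, seed=seed)
    if labels is None:
        return []
    valleys = minima[labels == 0]  # lower-valued cluster = squats
    vel = _boundary_velocity(z, rate, vel_window)

    squats: list[SquatSegment] = []
    bound = int(round(group_window_s * rate))  # max scan range around a valley
    for v in valleys:
        # the sampled valley frame can sit a frame off the true minimum, so
        # |vel| there may already exceed the tolerance; first step toward the
        # descent (left) / ascent (right), then traverse it to the crossing
        i = int(v)
        while i > max(0, v - bound) and vel[i] >= -vel_tol:
            i -= 1
        while i > max(0, v - bound) and vel[i] < -vel_tol:
            i -= 1
        j = int(v)
        while j < min(n - 1, v + bound) and vel[j] <= vel_tol:
            j += 1
        while j < min(n - 1, v + bound) and vel[j] > vel_tol:
            j += 1
        if not (i < v < j):
            continue
        depth = 0.5 * (z[i] + z[j]) - z[v]
        if depth <= 0:
            continue
        squats.append(SquatSegment(start=i, end=j, valley=int(v),
                                   duration=(j - i) / rate, depth=float(depth)))
    # enforce disjoint intervals (consecutive squats may share a shoulder)
    for a, b in zip(squats, squats[1:]):
        if a.end > b.start:
            mid = (a.valley + b.valley) // 2
            a.end = min(a.end, mid)
            b.start = max(b.start, mid)
            a.duration = (a.end - a.start) / rate
            b.duration = (b.end - b.start) / rate
    return squats


def group_valleys(valleys: np.ndarray, rate: float,
                  group_window_s: float = 8.0) -> list[np.ndarray]:
    """Group valley frames closer than ``group_window_s`` (burst structure)."""
    valleys = np.asarray(valleys, dtype=int)
    if len(valleys) == 0:
        return []
    splits = np.flatnonzero(np.diff(valleys) / rate >= group_window_s) + 1
    return np.split(valleys, splits)


def squat_metrics(squats: list[SquatSegment]) -> MetricsRecord | None:
    """Per-trial mean squat duration (s) and depth (m); None when empty."""
    if not squats:
        return None
    return MetricsRecord(
        source="", state="squatting",
        values={
            "squat_duration_s": float(np.mean([s.duration for s in squats])),
            "squat_depth_m": float(np.mean([s.depth for s in squats])),
        },
        n_segments=len(squats),
    )
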