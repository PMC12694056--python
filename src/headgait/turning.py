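"""Pivot-turn detection from yaw angular velocity (merged-turn scheme).

A turn is seeded at a peak of the filtered |yaw velocity| exceeding the
detection threshold Ve; its onset/offset are the nearest frames on either side
where |velocity| falls to the edge thresholds (Vx before the peak, Vc after).
Overlapping same-direction candidates are merged unless a sufficiently deep
velocity minimum (the "required depth") separates them.  Edge thresholds can
be optimized against reference turn durations by an exhaustive ICC(A,1) grid
search, mirroring how head-yaw thresholds are tuned against pelvis-yaw turns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks

from . import agreement
from .errors import InputError, InsufficientDataError, OptimizationError
from .segments import MetricsRecord
from .timeseries import derivative


@dataclass(frozen=True)
class TurnThresholds:
    """Velocity thresholds (deg/s) and filter span (s) for turn detection."""

    impulse_dur: float = 1.5   # moving-average impulse response duration
    min_depth: float = 20.0    # required dip below both flanking peaks to split
    ve: float = 50.0           # peak threshold to detect a turn
    vx: float = 18.0           # onset edge threshold
    vc: float = 39.0           # offset edge threshold

    def __post_init__(self):
        if not (self.ve > 0 and self.vx > 0 and self.vc > 0 and self.impulse_dur > 0):
            raise InputError("all turn thresholds must be positive")

    @classmethod
    def pelvis(cls) -> "TurnThresholds":
        """Defaults tuned for pelvis-yaw (reference) signals."""
        return cls(vx=18.0, vc=39.0)

    @classmethod
    def head(cls) -> "TurnThresholds":
        """Defaults tuned for head-yaw (AR) signals."""
        return cls(vx=26.0, vc=16.0)


@dataclass
class TurnSegment:
    """One detected turn: half-open frame interval + summary values."""

    start: int
    end: int
    direction: int        # sign of yaw velocity at the peak
    duration: float       # s, (end - start) / rate
    peak_velocity: float  # deg/s, from the filtered velocity
    peak_frame: int = 0


def filter_yaw_velocity(yaw: np.ndarray, rate: float,
                        impulse_dur: float = 1.5) -> np.ndarray:
    """Differentiate unwrapped yaw and low-pass it with a boxcar FIR.

    The kernel spans ``impulse_dur`` seconds and is applied centred (zero
    phase); edges are handled by replicate padding.  Units: deg/s.
    """
    vel = derivative(yaw, rate)
    k = int(round(impulse_dur * rate))
    if len(vel) < k:
        raise InsufficientDataError(f"series shorter than {impulse_dur}s kernel")
    pad_l = k // 2
    pad_r = k - 1 - pad_l
    padded = np.concatenate([np.full(pad_l, vel[0]), vel, np.full(pad_r, vel[-1])])
    return np.convolve(padded, np.ones(k) / k, mode="valid")


def detect_turns(vel: np.ndarray, th: TurnThresholds, rate: float) -> list[TurnSegment]:
    """Detect turns in a filtered yaw-velocity signal (see module docstring)."""
    vel = np.asarray(vel, dtype=float)
    speed = np.abs(vel)
    n = len(vel)
    peaks, _ = find_peaks(speed, height=th.ve)
    cands = []
    for p in peaks:
        i = p
        while i > 0 and speed[i] > th.vx:
            i -= 1
        j = p
        while j < n - 1 and speed[j] > th.vc:
            j += 1
        cands.append([i, j, int(p)])
    # merge / split overlapping candidates
    merged: list[list[int]] = []
    for c in cands:
        if merged and c[0] <= merged[-1][1]:
            prev = merged[-1]
            dip_sl = slice(prev[2], c[2] + 1)
            dip_frame = prev[2] + int(np.argmin(speed[dip_sl]))
            dip = speed[dip_frame]
            shallower_peak = min(speed[prev[2]], speed[c[2]])
            same_dir = np.sign(vel[prev[2]]) == np.sign(vel[c[2]])
            if same_dir and dip > shallower_peak - th.min_depth:
                # one continuous turn: extend, keep the taller peak
                prev[1] = max(prev[1], c[1])
                if speed[c[2]] > speed[prev[2]]:
                    prev[2] = c[2]
            else:
                # distinct turns separated at the velocity minimum
                prev[1] = min(prev[1], dip_frame)
                c[0] = max(c[0], dip_frame)
                merged.append(c)
        else:
            merged.append(c)
    out = []
    for i, j, p in merged:
        if j <= i:
            continue
        seg = TurnSegment(
            start=i, end=j, direction=int(np.sign(vel[p])),
            duration=(j - i) / rate,
            peak_velocity=float(speed[i:j + 1].max()),
            peak_frame=p,
        )
        out.append(seg)
    return out


def turn_metrics(turns: list[TurnSegment]) -> MetricsRecord | None:
    """Per-trial mean turn duration (s) and mean peak angular velocity (deg/s)."""
    if not turns:
        return None
    return MetricsRecord(
        source="", state="turning",
        values={
            "turn_duration_s": float(np.mean([t.duration for t in turns])),
            "peak_angular_velocity_dps": float(np.mean([t.peak_velocity for t in turns])),
        },
        n_segments=len(turns),
    )


def optimize_thresholds(ar_vels: list[np.ndarray], ref_durations: list,
                        rate: float, base: TurnThresholds,
                        grid: dict) -> tuple[TurnThresholds, float]:
    """Exhaustive edge-threshold grid search maximizing ICC(A,1) vs reference.

    ``ar_vels`` are per-trial filtered AR yaw velocities, ``ref_durations``
    the per-trial reference mean turn durations (None where undefined), and
    ``grid`` maps threshold field names (``vx``, ``vc``, ``ve``...) to value
    lists.  Ties are broken toward the lexicographically smallest (vx, vc).
    Raises OptimizationError when no combination leaves enough matched trials
    for an ICC.
    """
    if len(ar_vels) != len(ref_durations):
        raise InputError("ar_vels and ref_durations must be parallel lists")
    fields = sorted(grid)
    best = None
    for combo in itertools.product(*(grid[f] for f in fields)):
        th = replace(base, **dict(zip(fields, combo)))
        rows = []
        for vel, ref_d in zip(ar_vels, ref_durations):
            if ref_d is None:
                continue
            turns = detect_turns(vel, th, rate)
            if not turns:
                continue
            rows.append((float(np.mean([t.duration for t in turns])), float(ref_d)))
        if len(rows) < 3:
            continue
        res = agreement.icc(np.asarray(rows), form="A1")
        if res.degenerate:
            continue
        key = (res.value, -th.vx, -th.vc)
        if best is None or key > best[0]:
            best = (key, th, res.value)
    if best is None:
        raise OptimizationError("no threshold combination yielded enough matched trials")
    return best[1], best[2]
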