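"""Straight-walking detection and gait metrics.

Straight-walking bouts are found from the horizontal head trajectory and yaw:
a bout must cover more than 2 m of arc length, keep both the heading angle
range and the yaw range under 45 degrees, and sustain an instantaneous speed
above 0.5 m/s on every frame.  Spatiotemporal metrics come from two kinds of
gait events: heel strikes from the reference system's heel/toe channels (the
minimal-distance-between-heel-and-toe signal) and double-support events from
minima of the band-passed vertical head position, the head-only surrogate
available to the AR system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, detrend, find_peaks, sosfiltfilt

from .errors import InputError
from .segments import GaitEventList, MetricsRecord, MotorStateSegment
from .timeseries import PoseSeries


@dataclass
class HeadingSeries:
    """Per-frame heading (deg), cumulative arc length (m) and speed (m/s).

    The heading is the instantaneous orientation of the horizontal trajectory,
    computed on an arc-length re-parameterization (uniform 0.01 m steps) to
    decouple it from sampling density, then mapped back to frames by nearest
    arc position.  Where the trajectory is stationary the heading is NaN.
    """

    heading: np.ndarray
    arc_length: np.ndarray
    inst_speed: np.ndarray
    stationary: bool = False


def compute_heading(x: np.ndarray, y: np.ndarray, rate: float,
                    arc_step: float = 0.01) -> HeadingSeries:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2:
        raise InputError("need at least 2 frames for a trajectory")
    dx = np.gradient(x)
    dy = np.gradient(y)
    inst_speed = np.hypot(dx, dy) * rate
    step = np.hypot(np.diff(x), np.diff(y))
    s = np.concatenate([[0.0], np.cumsum(step)])
    if s[-1] < arc_step:
        return HeadingSeries(np.full_like(x, np.nan), s, inst_speed, stationary=True)

    # strictly increasing arc positions for interpolation (drop stationary runs)
    keep = np.concatenate([[True], np.diff(s) > 1e-12])
    su, xu, yu = s[keep], x[keep], y[keep]
    grid = np.arange(0.0, su[-1] + arc_step / 2, arc_step)
    xg = np.interp(grid, su, xu)
    yg = np.interp(grid, su, yu)
    heading_arc = np.degrees(np.unwrap(np.arctan2(np.diff(yg), np.diff(xg))))
    # nearest tangent for each frame's arc position
    idx = np.clip(np.round(s / arc_step).astype(int), 0, len(heading_arc) - 1)
    return HeadingSeries(heading_arc[idx], s, inst_speed)


def detect_straight_walking(series: PoseSeries, *, min_speed: float = 0.5,
                            max_heading_range: float = 45.0,
                            max_yaw_range: float = 45.0,
                            min_length_m: float = 2.0,
                            arc_step: float = 0.01) -> list[MotorStateSegment]:
    """Find maximal straight-walking segments satisfying all four criteria.

    Frames with speed above ``min_speed`` are grown into runs; each run is
    scanned left to right with a sliding anchor that splits whenever the
    cumulative heading or yaw range reaches the 45-degree limit.  Segments
    whose arc length does not exceed ``min_length_m`` are discarded.
    """
    hs = compute_heading(series.x, series.y, series.rate, arc_step)
    if hs.stationary:
        return []
    fast = hs.inst_speed > min_speed
    segments: list[MotorStateSegment] = []

    def emit(a: int, b: int):
        if b - a < 2:
            return
        if hs.arc_length[b - 1] - hs.arc_length[a] > min_length_m:
            segments.append(MotorStateSegment("straight_walking", a, b, series.source))

    n = len(series)
    i = 0
    while i < n:
        if not fast[i]:
            i += 1
            continue
        j = i
        while j < n and fast[j]:
            j += 1
        # scan run [i, j) splitting on angle ranges
        a = i
        h_lo = h_hi = hs.heading[a]
        y_lo = y_hi = series.yaw[a]
        for k in range(a + 1, j):
            h_lo = min(h_lo, hs.heading[k]); h_hi = max(h_hi, hs.heading[k])
            y_lo = min(y_lo, series.yaw[k]); y_hi = max(y_hi, series.yaw[k])
            if (h_hi - h_lo) >= max_heading_range or (y_hi - y_lo) >= max_yaw_range:
                emit(a, k)
                a = k
                h_lo = h_hi = hs.heading[a]
                y_lo = y_hi = series.yaw[a]
        emit(a, j)
        i = j
    return segments


def max_gait_speed(segment: MotorStateSegment, series: PoseSeries,
                   window_s: float = 0.5) -> float | None:
    """Peak of the centred moving-average (``window_s``) frame-to-frame speed.

    Returns None (metric undefined) for segments shorter than the window.
    """
    rate = series.rate
    w = int(round(window_s * rate))
    sl = slice(segment.start, segment.end)
    dx = np.gradient(series.x[sl])
    dy = np.gradient(series.y[sl])
    speed = np.hypot(dx, dy) * rate
    if len(speed) < w:
        return None
    filt = np.convolve(speed, np.ones(w) / w, mode="valid")
    return float(filt.max())


def detect_heel_strikes_mdht(heel_z: np.ndarray, toe_z: np.ndarray, rate: float,
                             *, prominence: float = 0.01,
                             min_peak_dist_s: float = 0.5,
                             search_s: tuple = (0.05, 0.5),
                             min_drop: float = 0.04,
                             max_abs: float = 0.05,
                             source: str = "") -> GaitEventList:
    """Heel strikes from the minimal distance between heel and toe (MDHT).

    ``heel_z``/``toe_z`` may be 1-D (single foot) or 2-D with one column per
    foot; per-foot events are merged and sorted.  A candidate peak of the
    heel-minus-toe signal is accepted when its closest preceding minimum
    (within ``search_s`` seconds) lies at least ``min_drop`` m below the peak
    and has absolute value under ``max_abs`` m; that minimum is the heel
    strike.
    """
    heel = np.atleast_2d(np.asarray(heel_z, dtype=float).T).T
    toe = np.atleast_2d(np.asarray(toe_z, dtype=float).T).T
    if heel.shape != toe.shape:
        raise InputError("heel and toe channels must have identical shape")
    events: set[int] = set()
    lo = max(1, int(round(search_s[0] * rate)))
    hi = int(round(search_s[1] * rate))
    for col in range(heel.shape[1]):
        mdht = heel[:, col] - toe[:, col]
        peaks, _ = find_peaks(mdht, prominence=prominence,
                              distance=int(round(min_peak_dist_s * rate)))
        minima, _ = find_peaks(-mdht)
        for p in peaks:
            prev = minima[(minima >= p - hi) & (minima <= p - lo)]
            if len(prev) == 0:
                continue
            m = int(prev[-1])  # closest preceding minimum (ties -> later)
            if mdht[p] - mdht[m] >= min_drop and abs(mdht[m]) < max_abs:
                events.add(m)
    frames = np.array(sorted(events), dtype=int)
    return GaitEventList(frames, kind="heel_strike", source=source)


def detect_double_support(z: np.ndarray, rate: float, *,
                          prominence: float = 0.001,
                          min_dist_frames: int = 13,
                          band_hz: tuple = (1.5, 3.5),
                          butter_order: int = 2,
                          source: str = "") -> GaitEventList:
    """Double-support events: minima of the band-passed vertical head position.

    The channel is linearly detrended and band-pass filtered (zero phase,
    Butterworth) around the expected step frequency before peak picking.
    Segments shorter than 1 s yield no events.
    """
    z = np.asarray(z, dtype=float)
    if len(z) < rate:
        return GaitEventList(np.array([], dtype=int), "double_support", source)
    zd = detrend(z)
    sos = butter(butter_order, band_hz, btype="bandpass", fs=rate, output="sos")
    zf = sosfiltfilt(sos, zd)
    minima, _ = find_peaks(-zf, prominence=prominence, distance=min_dist_frames)
    return GaitEventList(minima.astype(int), "double_support", source)


def step_metrics(events: GaitEventList, series: PoseSeries,
                 offset: int = 0) -> MetricsRecord | None:
    """Mean step length and cadence from consecutive gait events.

    Step length is the 2-D horizontal displacement between consecutive events;
    cadence converts the median inter-event interval into steps per minute.
    ``offset`` shifts event frames into the series' index space when the
    events were detected on a sub-slice.  Undefined (None) for < 2 events.
    """
    if len(events) < 2:
        return None
    f = events.frames + offset
    dx = np.diff(series.x[f])
    dy = np.diff(series.y[f])
    lengths = np.hypot(dx, dy)
    med = float(np.median(np.diff(f)))
    return MetricsRecord(
        source=series.source, state="straight_walking",
        values={
            "step_length_m": float(np.mean(lengths)),
            "cadence_spm": 60.0 * series.rate / med,
            "n_steps": int(len(lengths)),
        },
        n_segments=1,
    )
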