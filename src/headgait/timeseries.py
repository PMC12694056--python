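"""Head-pose time-series container, file I/O and shared preprocessing.

A trial is a uniformly (or nearly uniformly) sampled recording of the head's
horizontal position (x, y, metres), vertical position (z, metres, up positive)
and yaw angle (degrees, stored unwrapped).  Two sources are distinguished: the
AR glasses ("ar") and the reference motion-capture system ("ref").  All
detectors downstream assume series that have been resampled to a common rate,
gap-filled, smoothed and temporally aligned by the functions in this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import savgol_filter

from .errors import (
    AlignmentError,
    FormatError,
    InputError,
    InsufficientDataError,
    TrialExcludedError,
)

CORE_CHANNELS = ("x", "y", "z", "yaw")

#: Optional per-foot channels accepted in pose CSV files (reference system).
FOOT_CHANNELS = ("heel_l_z", "toe_l_z", "heel_r_z", "toe_r_z")


@dataclass
class PoseSeries:
    """Uniformly sampled 6-DoF head pose (position + yaw) of one source.

    ``missing_mask`` flags frames that were originally missing in the raw
    recording; their channel values are NaN until :func:`fill_missing_cubic`
    replaces them.  ``extras`` holds optional auxiliary channels such as the
    reference system's heel/toe vertical positions.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    yaw: np.ndarray
    rate: float
    source: str = "ar"
    missing_mask: np.ndarray = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.missing_mask is None:
            self.missing_mask = np.zeros(len(self.t), dtype=bool)
        n = len(self.t)
        for name in CORE_CHANNELS:
            if len(getattr(self, name)) != n:
                raise InputError(f"channel {name!r} length != time base length")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def missing_frac(self) -> float:
        return float(np.mean(self.missing_mask))

    def channel(self, name: str) -> np.ndarray:
        if name in CORE_CHANNELS or name == "t":
            return getattr(self, name)
        return self.extras[name]

    def take(self, sl: slice) -> "PoseSeries":
        """Return a view-like copy restricted to ``sl`` (keeps the time base)."""
        return PoseSeries(
            t=self.t[sl].copy(),
            x=self.x[sl].copy(),
            y=self.y[sl].copy(),
            z=self.z[sl].copy(),
            yaw=self.yaw[sl].copy(),
            rate=self.rate,
            source=self.source,
            missing_mask=self.missing_mask[sl].copy(),
            extras={k: v[sl].copy() for k, v in self.extras.items()},
        )


@dataclass
class TrialPair:
    """A pair of simultaneously recorded series (AR + reference).

    ``lag_frames`` is the shift applied by :func:`align_by_xcorr` to bring the
    reference onto the AR clock; ``game`` labels the exercise context, which
    decides which motor-state detectors apply.
    """

    ar: PoseSeries
    ref: PoseSeries
    lag_frames: int = 0
    game: str = ""


def _unwrap_deg(yaw: np.ndarray) -> np.ndarray:
    """Unwrap yaw in degrees, skipping NaN gaps."""
    out = np.asarray(yaw, dtype=float).copy()
    ok = np.isfinite(out)
    if ok.sum() >= 2:
        out[ok] = np.degrees(np.unwrap(np.radians(out[ok])))
    return out


def read_pose_csv(path, source: str = "ar") -> PoseSeries:
    """Read a pose CSV with columns ``t,x,y,z,yaw`` (foot columns optional).

    Blank cells mark missing samples; ``#`` starts a comment line.  The
    nominal rate is inferred from the median time step.  Non-uniform time
    bases are accepted (resampling handles them later).
    """
    df = pd.read_csv(path, comment="#")
    missing_cols = [c for c in ("t",) + CORE_CHANNELS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing required column(s) {missing_cols}")
    if len(df) < 2:
        raise InsufficientDataError(f"{path}: need at least 2 rows, got {len(df)}")
    t = df["t"].to_numpy(dtype=float)
    if np.any(~np.isfinite(t)):
        raise FormatError(f"{path}: non-numeric or blank values in column 't'")
    chans = {c: df[c].to_numpy(dtype=float) for c in CORE_CHANNELS}
    mask = np.zeros(len(df), dtype=bool)
    for c in CORE_CHANNELS:
        mask |= ~np.isfinite(chans[c])
    extras = {
        c: df[c].to_numpy(dtype=float) for c in df.columns
        if c not in ("t",) + CORE_CHANNELS
    }
    rate = 1.0 / float(np.median(np.diff(t)))
    return PoseSeries(
        t=t, x=chans["x"], y=chans["y"], z=chans["z"],
        yaw=_unwrap_deg(chans["yaw"]),
        rate=rate, source=source, missing_mask=mask, extras=extras,
    )


def write_pose_csv(series: PoseSeries, path) -> None:
    """Write a series in the CSV layout accepted by :func:`read_pose_csv`.

    Originally missing frames are written as blank cells.
    """
    cols = {"t": series.t}
    for c in CORE_CHANNELS:
        v = series.channel(c).astype(float).copy()
        v[series.missing_mask] = np.nan
        cols[c] = v
    for name, v in series.extras.items():
        cols[name] = v
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9g")


def resample_linear(series: PoseSeries, target_rate: float) -> PoseSeries:
    """Resample onto a uniform grid at ``target_rate`` by linear interpolation.

    The output grid spans the input time range starting at ``t[0]``.  A frame
    is flagged missing when either bracketing input sample was missing.
    """
    if target_rate <= 0:
        raise InputError("target_rate must be positive")
    t = series.t
    if np.any(np.diff(t) <= 0):
        raise InputError("time base must be strictly increasing")
    n = int(np.floor((t[-1] - t[0]) * target_rate + 1e-9)) + 1
    grid = t[0] + np.arange(n) / target_rate

    j = np.clip(np.searchsorted(t, grid, side="right") - 1, 0, len(t) - 1)
    exact = np.abs(grid - t[j]) <= 1e-9
    j_next = np.minimum(j + 1, len(t) - 1)
    mask = np.where(exact, series.missing_mask[j],
                    series.missing_mask[j] | series.missing_mask[j_next])

    def interp(v):
        return np.interp(grid, t, v)

    return PoseSeries(
        t=grid,
        x=interp(series.x), y=interp(series.y), z=interp(series.z),
        yaw=interp(series.yaw),
        rate=float(target_rate), source=series.source, missing_mask=mask,
        extras={k: interp(v) for k, v in series.extras.items()},
    )


def fill_missing_cubic(series: PoseSeries, max_missing_frac: float = 0.10) -> PoseSeries:
    """Replace missing frames by cubic-spline interpolation from valid frames.

    If the missing fraction exceeds ``max_missing_frac`` the trial is excluded
    (:class:`TrialExcludedError`), mirroring the 10%-missing-data rule.
    Leading/trailing missing frames are trimmed rather than extrapolated; the
    exclusion rule is evaluated before trimming.  The spline uses not-a-knot
    boundary conditions so an interior-gapped cubic is reproduced exactly.
    """
    frac = series.missing_frac
    if frac > max_missing_frac:
        raise TrialExcludedError(
            f"{series.source}: {frac:.1%} frames missing exceeds "
            f"{max_missing_frac:.0%} threshold", missing_frac=frac)
    out = series
    mask = series.missing_mask
    if mask.any():
        valid = np.flatnonzero(~mask)
        out = series.take(slice(valid[0], valid[-1] + 1))
        mask = out.missing_mask
        if mask.any():
            knots = np.flatnonzero(~mask)
            for name in CORE_CHANNELS:
                ch = out.channel(name)
                spl = CubicSpline(out.t[knots], ch[knots], bc_type="not-a-knot")
                ch[mask] = spl(out.t[mask])
    # extras may carry their own NaN runs independent of the core mask
    for name, ch in out.extras.items():
        bad = ~np.isfinite(ch)
        if bad.any() and (~bad).sum() >= 4:
            knots = np.flatnonzero(~bad)
            spl = CubicSpline(out.t[knots], ch[knots], bc_type="not-a-knot")
            ch[bad] = spl(out.t[bad])
    return out


def smooth_savgol(channel: np.ndarray, order: int = 2, window: int = 61) -> np.ndarray:
    """Savitzky-Golay smoothing (local least-squares polynomial fit).

    Near the edges the filter fits the polynomial on the available one-sided
    window (scipy's ``mode='interp'``) instead of mirror padding.
    """
    channel = np.asarray(channel, dtype=float)
    if window % 2 == 0 or window <= order:
        raise InputError("window must be odd and larger than the polynomial order")
    if len(channel) < window:
        raise InsufficientDataError(
            f"channel length {len(channel)} < window {window}")
    return savgol_filter(channel, window, order, mode="interp")


def smooth_series(series: PoseSeries, window: int = 61, order: int = 2,
                  window_vertical: int | None = None) -> PoseSeries:
    """Smooth all channels of a series in place-like fashion (returns a copy).

    Horizontal position and yaw use ``window``; vertical channels (head z and
    any heel/toe z) use ``window_vertical`` when given.  Vertical channels
    carry the sharpest motor-state boundaries (squat/transfer onsets, gait
    events), where a long window smears movement tails past the stillness
    threshold and attenuates the step-frequency oscillation.
    """
    wv = window_vertical or window
    out = series.take(slice(None))
    out.x = smooth_savgol(out.x, order, window)
    out.y = smooth_savgol(out.y, order, window)
    out.yaw = smooth_savgol(out.yaw, order, window)
    out.z = smooth_savgol(out.z, order, wv)
    for name in list(out.extras):
        out.extras[name] = smooth_savgol(out.extras[name], order, wv)
    return out


def detrend_offset(channel: np.ndarray) -> np.ndarray:
    """Remove the constant offset (mean) of a channel."""
    channel = np.asarray(channel, dtype=float)
    return channel - channel.mean()


def derivative(channel: np.ndarray, rate: float) -> np.ndarray:
    """First derivative: central differences inside, one-sided at the ends."""
    channel = np.asarray(channel, dtype=float)
    if len(channel) < 3:
        raise InputError("need at least 3 samples to differentiate")
    return np.gradient(channel, 1.0 / rate)


def align_by_xcorr(pair: TrialPair, max_lag_s: float = 5.0,
                   min_overlap_s: float = 1.0) -> TrialPair:
    """Align the reference to the AR clock by vertical-position cross-correlation.

    The lag maximizing the cross-correlation of the mean-removed z channels
    (searched within ``+/- max_lag_s``) is applied to the reference; both
    series are trimmed to the common overlapping window.  ``lag_frames`` > 0
    means the reference recording lags the AR clock.
    """
    ar, ref = pair.ar, pair.ref
    if abs(ar.rate - ref.rate) > 1e-6:
        raise InputError("both series must share the sampling rate before alignment")
    rate = ar.rate
    az = detrend_offset(ar.z)
    rz = detrend_offset(ref.z)
    kmax = int(round(max_lag_s * rate))
    best_k, best_c = 0, -np.inf
    for k in range(-kmax, kmax + 1):
        if k >= 0:
            L = min(len(az), len(rz) - k)
            if L < int(min_overlap_s * rate):
                continue
            c = float(np.dot(az[:L], rz[k:k + L]))
        else:
            L = min(len(az) + k, len(rz))
            if L < int(min_overlap_s * rate):
                continue
            c = float(np.dot(az[-k:-k + L], rz[:L]))
        if c > best_c:
            best_c, best_k = c, k
    k = best_k
    if k >= 0:
        L = min(len(ar), len(ref) - k)
        ar_sl, ref_sl = slice(0, L), slice(k, k + L)
    else:
        L = min(len(ar) + k, len(ref))
        ar_sl, ref_sl = slice(-k, -k + L), slice(0, L)
    if L < int(min_overlap_s * rate):
        raise AlignmentError(f"only {L / rate:.2f}s overlap after alignment")
    ar2 = ar.take(ar_sl)
    ref2 = ref.take(ref_sl)
    ref2.t = ar2.t.copy()  # reference re-indexed onto the AR clock
    return TrialPair(ar=ar2, ref=ref2, lag_frames=k, game=pair.game)
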