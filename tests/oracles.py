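"""Independent reference computations used to check the implementation.

These deliberately avoid the package's own code paths: closed forms, direct
per-window least squares, explicit ANOVA sums and exhaustive enumeration.
"""

import itertools

import numpy as np


def savgol_per_window(channel, order, window):
    """Interior Savitzky-Golay smoothing by an explicit polynomial fit
    per window, evaluated at the window centre."""
    half = window // 2
    out = np.full(len(channel), np.nan)
    idx = np.arange(-half, half + 1)
    for i in range(half, len(channel) - half):
        coef = np.polynomial.polynomial.polyfit(idx, channel[i - half:i + half + 1],
                                                order)
        out[i] = coef[0]
    return out


def moving_average_max(values, window):
    """Brute-force maximum of the full-window moving average."""
    best = -np.inf
    for i in range(len(values) - window + 1):
        best = max(best, np.mean(values[i:i + window]))
    return best


def turn_profile(angle, duration, impulse_dur, dt=1e-4):
    """Closed-form boxcar-filtered yaw velocity of a raised-cosine turn.

    The filtered velocity at time tau equals the yaw change across the
    (clamped) window divided by its span.  Returns (t, filtered_velocity).
    """

    def yaw(t):
        t = np.clip(t, 0.0, duration)
        return angle * (1 - np.cos(np.pi * t / duration)) / 2

    half = impulse_dur / 2
    t = np.arange(-impulse_dur, duration + impulse_dur, dt)
    vel = (yaw(t + half) - yaw(t - half)) / impulse_dur
    return t, vel


def turn_crossings(angle, duration, ve, vx, vc, impulse_dur):
    """Analytic onset/offset times of one filtered raised-cosine turn."""
    t, vel = turn_profile(angle, duration, impulse_dur)
    speed = np.abs(vel)
    p = int(np.argmax(speed))
    assert speed[p] >= ve
    i = p
    while speed[i] > vx:
        i -= 1
    j = p
    while speed[j] > vc:
        j += 1
    return t[i], t[j], speed[p]


def anova_icc(table, form):
    """ICC via explicit double-loop ANOVA sums of squares."""
    n, k = table.shape
    grand = sum(table[i][j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(table[i][j] for j in range(k)) / k for i in range(n)]
    col = [sum(table[i][j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((r - grand) ** 2 for r in row)
    ssc = n * sum((c - grand) ** 2 for c in col)
    sst = sum((table[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if form == "C1":
        return (msr - mse) / (msr + (k - 1) * mse)
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


def match_counts_bruteforce(ar, ref, min_overlap=0.5):
    """Exhaustive one-to-one assignment of best-match claims.

    Each AR segment may only be matched to its highest-overlap reference
    segment (earlier segment on ties) and only when that overlap reaches
    ``min_overlap``; subject to one AR claim per reference segment, the
    assignment maximizing (matches, total overlap) is found by enumerating
    every subset of claims.  Returns (tp, fp, fn).
    """
    claims = []
    for ia, a in enumerate(ar):
        best_ov, best_ir = 0.0, None
        for ir, r in enumerate(ref):
            inter = max(0, min(a[1], r[1]) - max(a[0], r[0]))
            ov = inter / (a[1] - a[0])
            if ov > best_ov:
                best_ov, best_ir = ov, ir
        if best_ir is not None and best_ov >= min_overlap:
            claims.append((ia, best_ir, best_ov))
    best = (0, 0.0)
    for size in range(len(claims), -1, -1):
        for subset in itertools.combinations(claims, size):
            ars = [c[0] for c in subset]
            refs = [c[1] for c in subset]
            if len(set(ars)) < len(ars) or len(set(refs)) < len(refs):
                continue
            cand = (len(subset), sum(c[2] for c in subset))
            if cand > best:
                best = cand
        if best[0] == size and size > 0:
            break
    tp = best[0]
    return tp, len(ar) - tp, len(ref) - tp
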