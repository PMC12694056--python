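# Methods

This note documents the models, parameters and numerical choices behind
`headgait`, and what the synthetic-data tests do and do not establish.

## Signal model

A trial is a pair of simultaneous recordings of the same movement: the head's
horizontal position (x, y in metres), vertical position (z, up positive) and
yaw angle (degrees), sampled at 50–100 Hz by two systems — a head-worn
tracker ("AR") and a laboratory reference ("ref"). The two systems differ by
constant per-channel offsets (different coordinate origins), a clock lag,
sampling rate, additive noise, and possibly missing reference frames. All
analysis happens on a common 50 Hz working grid after preprocessing; every
frame-count parameter below is interpreted at 50 Hz.

## Preprocessing

1. **Resampling** to 50 Hz by linear interpolation. Output frames whose
   bracketing input samples include a missing sample inherit the missing
   flag.
2. **Gap filling**: missing frames are replaced by a cubic spline fitted to
   the valid frames. A trial whose missing fraction exceeds 10% is excluded
   (the rule is evaluated before any trimming). Leading/trailing missing
   frames are trimmed, never extrapolated — spline extrapolation is
   unstable. The spline uses not-a-knot boundary conditions, which reproduce
   an interior-gapped cubic exactly; a natural spline would not.
3. **Smoothing**: Savitzky–Golay, 2nd-order polynomial. Horizontal position
   and yaw use a 61-frame (1.22 s) window. Vertical channels (head z,
   heel/toe z) use a short 11-frame window instead: the 61-frame window's
   impulse response keeps |dz/dt| above the 0.001 m/s stillness threshold
   for ≈ 0.55 s beyond each true movement edge (measured on a clean 1.2 s
   transfer ramp the detected duration becomes 2.32 s), and it inverts a
   2 Hz head-bounce oscillation (gain ≈ 0.2 with sign flip), which would
   corrupt double-support event polarity. Boundary handling is a one-sided
   polynomial fit near the edges (no mirror padding). Gap filling precedes
   smoothing; both orders are defensible, this one avoids smoothing across
   interpolated plateaus. Window sizes are configurable
   (`preprocess.savgol.window`, `preprocess.savgol.window_vertical`).
4. **Alignment**: the lag maximizing the cross-correlation of the two
   mean-removed vertical-position channels is applied to the reference,
   searched within ±5 s (an unbounded search risks spurious maxima). Both
   series are then trimmed to the common window; < 1 s of overlap is an
   error.

## Detectors

**Straight walking.** The heading angle is the orientation of the horizontal
trajectory tangent, computed on a 0.01 m arc-length re-parameterization
(decoupling it from sampling density) and mapped back to frames. Candidate
segments are maximal runs of frames with instantaneous speed > 0.5 m/s,
scanned left-to-right with an anchor that splits whenever the running heading
or yaw range reaches 45°; segments with arc length ≤ 2 m are discarded. The
enumeration is deterministic; the greedy split is one of several defensible
readings of "maximal segments satisfying all criteria".

**Gait events and metrics.** Max gait speed is the peak of a centred 0.5 s
moving average of frame-to-frame 2-D speed (full windows only). Reference
heel strikes use the minimal distance between heel and toe (MDHT = heel z −
toe z), per foot: peaks with ≥ 0.01 prominence and ≥ 0.5 s spacing; the
closest preceding minimum within 0.05–0.5 s is a heel strike iff it lies
≥ 0.04 m below the peak and |value| < 0.05 m; feet are detected separately
and merged (avoids cross-foot interference). The head-only route detects
double-support events as minima (prominence ≥ 0.001, spacing ≥ 13 frames) of
the linearly detrended, 1.5–3.5 Hz band-passed vertical position
(2nd-order Butterworth, zero phase — order is a convention; zero phase
preserves event timing). Step length is the horizontal displacement between
consecutive events; cadence = 60·rate / median(inter-event frames). The
median makes cadence robust to a single missed event.

**Turning.** Yaw is differentiated (central differences) and smoothed with a
zero-phase boxcar whose impulse response spans 1.5 s (the simplest filter
with a defined impulse-response duration; a Gaussian is configurable). Turns
are seeded at |ω| peaks ≥ Ve = 50°/s; the onset is the last frame before the
peak where |ω| falls to Vx, the offset the first frame after the peak where
it falls to Vc (Vx = 18, Vc = 39°/s for pelvis-like reference signals;
Vx = 26, Vc = 16°/s for head signals — head yaw is noisier and sharper).
Which edge threshold bounds onset vs. offset is a convention
(`turning.edge_roles` ambiguity documented here; onset = Vx). Overlapping
same-direction candidates merge unless the |ω| dip between them lies
≥ 20°/s below both flanking peaks (relative depth; an absolute mode is
configurable); opposite-direction or deeply-dipped neighbours split at the
velocity minimum. Peak angular velocity is read from the filtered velocity.
Turn boundaries are definitional: because the 1.5 s filter smears velocity
beyond the yaw ramp, the detected onset precedes the kinematic ramp start by
≈ 0.24 s (reference thresholds) — tests therefore compare detected
boundaries with the analytic edge-threshold crossing times of the filtered
profile, not with the raw ramp. `optimize_thresholds` evaluates a finite
edge-threshold grid exhaustively and returns the combination maximizing
ICC(A,1) between AR and reference per-trial mean durations (ties resolve to
the smallest (Vx, Vc)).

**Squats.** Local minima of z (prominence 0.02 m, spacing 1 s — peak-picking
defaults chosen for 0.2–0.6 m squats, configurable) are clustered by
two-cluster k-means on their values; the lower cluster is "squats". K-means
initialization is deterministic (centres at the min and max of the minima
values, ≤ 10 Lloyd iterations), so labels are reproducible without a seed;
the seed parameter is kept for API symmetry. Valleys closer than 8 s form
one burst but each valley is bounded individually. Boundaries are
vertical-velocity zero crossings (|v| ≤ 0.001 m/s) found by scanning outward
from the valley; since the sampled valley frame can sit one frame off the
true minimum (where |v| already exceeds 1 mm/s), the scan first steps toward
the descent/ascent and then traverses it. Depth = mean(z at start, z at
end) − min z. Consecutive squats sharing a shoulder are split at the
midpoint between valleys.

**Transfers.** All frames are clustered on z (same deterministic k-means);
the higher-centroid cluster is standing; centroid gaps < 0.1 m mean a
unimodal trial with no transfers. Sit-to-stand runs from the last frame
before a standing run with |vertical speed| < 0.001 m/s to the first such
frame inside it; stand-to-sit mirrors this at the run's end. The threshold
is applied to |speed| (signed vs. absolute is unstated in the field; absolute
is symmetric). Transfers truncated by the recording boundary are discarded
(their duration would be censored). The boundary velocity for squats and
transfers is a short 5-frame Savitzky–Golay derivative: longer windows
systematically extend clean-signal durations (7 frames: +6.7% on a 1.2 s
ramp; 61 frames: +93%).

**Matching.** For each AR segment, the reference segment with the highest
overlap (shared frames / AR length) is the best match, valid at ≥ 50%. A
reference segment satisfies at most one AR segment: on contested claims the
higher overlap wins and the loser is a false positive (the one-to-one
constraint is an interpretation that keeps TP + FP = #AR and
TP + FN = #ref). Ties resolve to the earlier reference segment.

**Agreement statistics.** ICC(C,1) and ICC(A,1) by two-way ANOVA
decomposition with McGraw–Wong F-based confidence intervals (verified to
machine precision against pingouin). Note ICC(A,1) ≤ ICC(C,1) holds only
when the between-column mean square exceeds the error mean square; the
converse case is possible and both are reported as computed. SEM uses the
average of the two systems' SDs (both per-system SEMs are also derivable
from the report); difference direction is reference − AR. Frame-wise
time-series consistency treats frames as rows and reports ICC(C,1) with a
plain F-interval — no autocorrelation correction, so those CIs are
anti-conservative for strongly autocorrelated channels (documented
limitation). RMSE intervals use the χ² distribution of the summed squared
errors (normal-error approximation). The paired bias test is a t-test when
Shapiro–Wilk does not reject normality of the differences at α = 0.05, else
a Wilcoxon signed-rank test; all-zero differences report statistic 0, p = 1
by convention.

## Synthetic data

The generator builds a clean reference trajectory from piecewise templates
and derives the AR series from the *same* motion: offsets (defaults
x +0.30 m, y −0.20 m, z +0.04 m, yaw +15°), a 0.4 s clock lag, 60 Hz AR vs.
50 Hz reference sampling, optional white noise, an optional per-participant
AR vertical excursion scale (emulating headset origin/pitch effects on
vertical displacement), and optional missing reference frames.

Defaults are chosen as a typical mild-to-moderate-impairment gait profile:
walking 1.2 m/s cruise with raised-cosine 0.8 s speed ramps, 2 steps/s with
a 0.02 m vertical head bounce at step frequency (inverted-pendulum-like head
motion), 8 m bouts; 180° pivot turns over 2 s (raised-cosine yaw ramp while
stationary); squats 0.4 m deep over 2 s with 0.06 m shallow distractor dips
(so the deep/shallow clustering is well posed); sit 1.20 m / stand 1.55 m
head heights with 1.2 s transfer ramps. Synthetic heel/toe channels place a
qualified MDHT minimum (−0.01 m dip) at each true heel-strike time with a
0.12 m peak 0.15 s later. Ground-truth walking boundaries are where the
analytic speed profile crosses 0.5 m/s (the detector's own criterion).
Between-participant jitter SDs (speed 0.25 m/s, step rate 0.2 Hz, squat
depth 0.17 m, durations 0.2–0.5 s, truncated to detector-compatible ranges)
match the spread such cohorts show in practice.

For cohort-level ICC evaluation, the per-participant AR vertical scale
s ~ N(1, σs) induces a depth error σe = σs·√(μd² + σb²); with both systems'
cells decomposed two-way, the population squat-depth
ICC(A,1) = σb² / (σb² + σe²/2). `depth_icc_calibration(0.9)` inverts this to
σs ≈ 0.18 so the cohort's true ICC is 0.9 by construction; detection noise
adds a small extra error, so estimates centre slightly below 0.9 with
15-participant CIs comfortably covering it.

What the synthetic tests do **not** show: the templates are noise-free or
white-noise-corrupted raised cosines; real signals carry low-frequency
tracking drift, head motions unrelated to the torso (scanning, nodding),
non-stationary gait, and reference-system soft-tissue/model artifacts. The
stillness-threshold boundary scans in particular behave differently on
signals whose noise floor exceeds 1 mm/s; passing recovery tests here
establishes algorithmic correctness, not field accuracy.

## Problem sizes and runtime

Recovery tests use single 60 s trials; classification cohorts use 5
participants × 4 protocols at 50 s; the ICC Monte-Carlo uses 20 seeds × 15
participants × 45 s squat trials. The full suite runs in well under a
minute on one CPU; `scripts/acceptance.py` in a few seconds.

## Known limitations

- Head-only double-support events are an indirect surrogate for foot
  contact; cadence agreement between routes is inherently looser than for
  spatial metrics.
- Peak yaw velocity from a head tracker is inflated by head-only motion;
  the generator does not model scanning, so this bias is not reproduced.
- Squat depth from a head tracker is sensitive to headset origin/pitch;
  the vertical-scale term models it statistically, and no correction is
  applied.
- From head height alone a deep squat is indistinguishable from sitting, so
  the transfer detector only runs in transfer-type exercise contexts (the
  `mixed` context maps to walking/turning/squatting).
- The turn detector targets fast pivot-like turns; thresholds are not tuned
  for slow free-living turning, and no turn-angle estimation is attempted.
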