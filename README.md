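# headgait

Motor-state segmentation and mobility metrics from 6-DoF head-pose time
series, with the between-system statistics needed to validate a head-worn
tracker (e.g. AR glasses using vSLAM self-tracking) against a laboratory
motion-capture reference.

AR-based neurorehabilitation platforms continuously record the head's 3-D
position and yaw orientation. For clinicians and movement scientists this
stream is an unobtrusive motion-capture signal: from it one can recover *when*
a person was walking, turning, squatting, or standing up, and *how well* —
step length, gait speed, cadence, turn duration and peak angular velocity,
squat depth and duration, and sit-to-stand/stand-to-sit durations. `headgait`
implements the full chain:

- **Preprocessing** — resampling to a 50 Hz working grid (linear
  interpolation), cubic-spline gap filling with a 10%-missing exclusion rule,
  Savitzky–Golay smoothing (2nd order, 61-frame window for horizontal/yaw
  channels), and temporal alignment of the two systems by cross-correlating
  the vertical head position.
- **Straight walking** — maximal segments with arc length > 2 m, heading
  range < 45°, yaw range < 45°, and instantaneous speed > 0.5 m/s throughout.
  Max gait speed is the peak of a 0.5 s moving-average of frame-to-frame
  speed. Heel strikes come from the minimal-distance-between-heel-and-toe
  (MDHT) signal of the reference system's foot channels; the head-only route
  uses double-support events (minima of the 1.5–3.5 Hz band-passed vertical
  position). Step length is the horizontal displacement between consecutive
  events; cadence converts the median inter-event interval to steps/min.
- **Turning** — a merged-turn detector on the boxcar-filtered (1.5 s impulse
  response) yaw angular velocity: turns are seeded at |ω| peaks ≥ Ve = 50°/s
  and bounded by edge thresholds (Vx/Vc; 18/39°/s for pelvis-like reference
  signals, 26/16°/s for head signals), with a 20°/s minimum dip required to
  separate consecutive turns. Edge thresholds can be re-optimized against
  reference durations by an exhaustive ICC(A,1) grid search.
- **Squats** — k-means (k = 2) clustering of vertical-position minima into
  deep squats vs. shallow dips; each squat is bounded by vertical-velocity
  zero crossings, giving duration and depth (baseline minus valley).
- **Transfers** — k-means clustering of the vertical position into
  sitting/standing; each standing run is bracketed by sit-to-stand and
  stand-to-sit intervals bounded by a 0.001 m/s stillness threshold on the
  vertical speed.
- **Matching & validity** — AR segments are matched to reference segments by
  ≥ 50% frame overlap (one-to-one), giving TP/FP/FN, precision, recall and
  F1 per motor state; paired per-participant metrics are compared with
  ICC(C,1)/ICC(A,1) (two-way single-rater, McGraw–Wong confidence
  intervals), RMSE, Bland–Altman bias and limits of agreement
  (bias ± 1.96·SD), SEM = SD·√(1 − ICC), and a Shapiro–Wilk-gated paired
  t-test / Wilcoxon signed-rank test.
- **Synthetic trials** — a generator of paired AR/reference recordings with
  analytic ground truth (walking bouts with head bounce and foot channels,
  raised-cosine pivot turns, squat dips, sit/stand plateaus; inter-system
  offsets, lag, rate differences, noise, missing samples), so the whole
  pipeline is testable without any recorded data.

## Worked example

```sh
headgait simulate --protocol squat --duration 45 --seed 3 --out trial/
echo "participant,game,ar_csv,ref_csv
0,squat,trial/ar.csv,trial/ref.csv" > manifest.csv
headgait run --manifest manifest.csv --out report/
python - <<'EOF'
import json
rep = json.load(open("report/report.json"))
print(rep["classification"]["squatting"])
EOF
```

prints (abridged):

```
{'state': 'squatting', 'tp': 4, 'fp': 0, 'fn': 0, 'precision': 1.0,
 'recall': 1.0, 'f1': 1.0, 'mean_overlap': 1.0, ...}
```

i.e. all four simulated squats were found by both the AR and the reference
route and every AR segment fully overlapped its reference counterpart. The
accompanying `metric_pairs.csv` holds the per-participant paired squat depth
and duration from which the agreement report (ICC, bias, limits of
agreement, SEM) is computed.

The same workflow applies to recorded data: any CSV with columns
`t,x,y,z,yaw` (and optional heel/toe columns for the reference system) can be
fed to `headgait segment`, `match`, `validate` or `run`. Every numeric
constant is overridable through a YAML config (`--config`).

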