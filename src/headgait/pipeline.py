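"""End-to-end orchestration: preprocess, detect, match, measure, validate.

``run_pipeline`` consumes trial pairs (one AR + one reference series each,
with a participant id and an exercise-context label), applies the shared
preprocessing, runs the detectors the context calls for, matches segments
between systems, derives mobility metrics on true-positive overlaps, and
aggregates classification (precision/recall/F1) and agreement (ICC, bias,
limits of agreement, SEM) reports across the cohort.  The pipeline is a pure
function of (config, inputs): repeated runs give identical reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import agreement, gait, matching, squats as squats_mod, transfers as transfers_mod, turning
from .config import PipelineConfig
from .errors import TrialExcludedError
from .segments import MotorStateSegment
from .timeseries import (
    PoseSeries,
    TrialPair,
    align_by_xcorr,
    fill_missing_cubic,
    resample_linear,
    smooth_series,
)

log = logging.getLogger("headgait")


@dataclass
class Trial:
    participant: int
    game: str
    pair: TrialPair


@dataclass
class PipelineResult:
    classification: dict = field(default_factory=dict)  # state -> ClassificationReport
    agreement: dict = field(default_factory=dict)       # metric -> AgreementReport
    metric_table: pd.DataFrame = None
    excluded: list = field(default_factory=list)        # (participant, game, reason)
    segments: list = field(default_factory=list)        # per-trial segment rows

    def to_dict(self) -> dict:
        return {
            "classification": {s: r.to_dict() for s, r in self.classification.items()},
            "agreement": {m: r.to_dict() for m, r in self.agreement.items()},
            "excluded": self.excluded,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=_jsonify)


def _jsonify(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def preprocess_pair(pair: TrialPair, cfg: PipelineConfig) -> TrialPair:
    """Resample to the working rate, fill gaps, smooth, and align."""
    pp = cfg.preprocess

    def prep(series: PoseSeries) -> PoseSeries:
        s = resample_linear(series, pp.target_rate)
        s = fill_missing_cubic(s, pp.max_missing_frac)
        return smooth_series(s, window=pp.savgol_window, order=pp.savgol_order,
                             window_vertical=pp.savgol_window_vertical)

    prepped = TrialPair(ar=prep(pair.ar), ref=prep(pair.ref), game=pair.game)
    return align_by_xcorr(prepped, max_lag_s=pp.xcorr_max_lag_s,
                          min_overlap_s=pp.min_overlap_s)


def detect_state(series: PoseSeries, state: str, cfg: PipelineConfig,
                 role: str) -> list:
    """Run one state's detector; returns detector-native segment objects."""
    rate = series.rate
    if state == "straight_walking":
        g = cfg.gait
        return gait.detect_straight_walking(
            series, min_speed=g.min_speed, max_heading_range=g.max_heading_range,
            max_yaw_range=g.max_yaw_range, min_length_m=g.min_length_m,
            arc_step=g.arc_step_m)
    if state == "turning":
        tc = cfg.turning
        th = turning.TurnThresholds(
            impulse_dur=tc.impulse_dur_s, min_depth=tc.min_depth, ve=tc.ve,
            vx=tc.ar_vx if role == "ar" else tc.ref_vx,
            vc=tc.ar_vc if role == "ar" else tc.ref_vc)
        vel = turning.filter_yaw_velocity(series.yaw, rate, th.impulse_dur)
        return turning.detect_turns(vel, th, rate)
    if state == "squatting":
        sq = cfg.squats
        return squats_mod.detect_squats(
            series.z, rate, prominence=sq.prominence_m, min_dist_s=sq.min_dist_s,
            group_window_s=sq.group_window_s, kmeans_iters=sq.kmeans_iters,
            vel_tol=sq.vel_tol, vel_window=sq.vel_window)
    if state == "transfers":
        tr = cfg.transfers
        return transfers_mod.detect_transfers(
            series.z, rate, speed_threshold=tr.speed_threshold,
            min_centroid_gap=tr.min_centroid_gap,
            kmeans_iters=tr.kmeans_iters, vel_window=tr.vel_window)
    raise ValueError(f"unknown state {state!r}")


def _as_match_segments(objs: list, state: str, source: str,
                       kind: str | None = None) -> list[MotorStateSegment]:
    """Normalize detector-native objects to MotorStateSegments for matching."""
    out = []
    for o in objs:
        if isinstance(o, MotorStateSegment):
            out.append(o)
        elif kind is None or getattr(o, "kind", None) == kind:
            out.append(MotorStateSegment(state, o.start, o.end, source))
    return out


def _walking_metric_rows(trial, a_seg, r_seg, pair, cfg) -> list:
    """Gait metrics on the overlapping frames of one matched walking pair."""
    g = cfg.gait
    rate = pair.ar.rate
    s = max(a_seg.start, r_seg.start)
    e = min(a_seg.end, r_seg.end)
    clip = MotorStateSegment("straight_walking", s, e)
    rows = []
    ar_max = gait.max_gait_speed(clip, pair.ar, g.speed_ma_window_s)
    ref_max = gait.max_gait_speed(clip, pair.ref, g.speed_ma_window_s)
    rows.append((trial.participant, "max_gait_speed_mps", ar_max, ref_max))
    # AR: double-support minima of the vertical head position
    ds = gait.detect_double_support(
        pair.ar.z[s:e], rate, prominence=g.ds_prominence,
        min_dist_frames=g.ds_min_dist_frames, band_hz=g.ds_band_hz,
        butter_order=g.butter_order, source="ar")
    ar_steps = gait.step_metrics(ds, pair.ar, offset=s)
    # reference: MDHT heel strikes when foot channels are available,
    # otherwise the same head-based double-support surrogate
    ref_series = pair.ref
    if {"heel_l_z", "toe_l_z", "heel_r_z", "toe_r_z"} <= set(ref_series.extras):
        heel = np.column_stack([ref_series.extras["heel_l_z"][s:e],
                                ref_series.extras["heel_r_z"][s:e]])
        toe = np.column_stack([ref_series.extras["toe_l_z"][s:e],
                               ref_series.extras["toe_r_z"][s:e]])
        hs = gait.detect_heel_strikes_mdht(
            heel, toe, rate, prominence=g.mdht_prominence,
            min_peak_dist_s=g.mdht_min_dist_s, search_s=g.mdht_search_s,
            min_drop=g.mdht_min_drop, max_abs=g.mdht_max_abs, source="ref")
    else:
        hs = gait.detect_double_support(
            ref_series.z[s:e], rate, prominence=g.ds_prominence,
            min_dist_frames=g.ds_min_dist_frames, band_hz=g.ds_band_hz,
            butter_order=g.butter_order, source="ref")
    ref_steps = gait.step_metrics(hs, ref_series, offset=s)
    for key in ("step_length_m", "cadence_spm"):
        rows.append((trial.participant, key,
                     ar_steps.get(key) if ar_steps else None,
                     ref_steps.get(key) if ref_steps else None))
    return rows


def run_pipeline(cfg: PipelineConfig, trials: list[Trial]) -> PipelineResult:
    result = PipelineResult()
    counts: dict = {}
    overlaps: dict = {}
    rows: list = []
    for trial in trials:
        try:
            pair = preprocess_pair(trial.pair, cfg)
        except TrialExcludedError as exc:
            log.warning("trial excluded (participant %s, %s): %s",
                        trial.participant, trial.game, exc)
            result.excluded.append((trial.participant, trial.game, str(exc)))
            continue
        for state in cfg.states_for(trial.game):
            ar_objs = detect_state(pair.ar, state, cfg, "ar")
            ref_objs = detect_state(pair.ref, state, cfg, "ref")
            sub_states = ([("sit_to_stand", "sit_to_stand"),
                           ("stand_to_sit", "stand_to_sit")]
                          if state == "transfers" else [(state, None)])
            for label, kind in sub_states:
                ar_segs = _as_match_segments(ar_objs, label, "ar", kind)
                ref_segs = _as_match_segments(ref_objs, label, "ref", kind)
                rep = matching.match_segments(
                    ar_segs, ref_segs, cfg.matching.min_overlap, state=label)
                c = counts.setdefault(label, [0, 0, 0])
                c[0] += rep.tp; c[1] += rep.fp; c[2] += rep.fn
                overlaps.setdefault(label, []).extend(m[2] for m in rep.matches)
                for seg in ar_segs + ref_segs:
                    result.segments.append(
                        (trial.participant, trial.game, seg.source, label,
                         seg.start, seg.end))
                rows.extend(_metric_rows(trial, label, state, rep, ar_objs,
                                         ref_objs, pair, cfg))
    for label, (tp, fp, fn) in counts.items():
        ovs = np.array(overlaps[label]) if overlaps[label] else np.array([])
        precision = tp / (tp + fp) if tp + fp else None
        recall = tp / (tp + fn) if tp + fn else None
        f1 = (2 * precision * recall / (precision + recall)
              if precision and recall else (0.0 if precision is not None and recall is not None else None))
        result.classification[label] = matching.ClassificationReport(
            state=label, tp=tp, fp=fp, fn=fn, precision=precision,
            recall=recall, f1=f1,
            mean_overlap=float(ovs.mean()) if len(ovs) else None,
            overlap_sd=float(ovs.std(ddof=1)) if len(ovs) > 1 else None)
    table = matching.metric_pairs(rows)
    result.metric_table = table
    if len(table):
        for metric, sub in table.groupby("metric"):
            if len(sub) >= 3:
                result.agreement[metric] = agreement.agreement_report(
                    sub[["ar", "ref"]].to_numpy(), form="A1")
    return result


def _metric_rows(trial, label, state, rep, ar_objs, ref_objs, pair, cfg) -> list:
    """Per-matched-pair metric rows for one state in one trial."""
    rows = []
    for a_seg, r_seg, _ov in rep.matches:
        if state == "straight_walking":
            rows.extend(_walking_metric_rows(trial, a_seg, r_seg, pair, cfg))
        elif state == "turning":
            a = _find_native(ar_objs, a_seg)
            r = _find_native(ref_objs, r_seg)
            rows.append((trial.participant, "turn_duration_s", a.duration, r.duration))
            rows.append((trial.participant, "peak_angular_velocity_dps",
                         a.peak_velocity, r.peak_velocity))
        elif state == "squatting":
            a = _find_native(ar_objs, a_seg)
            r = _find_native(ref_objs, r_seg)
            rows.append((trial.participant, "squat_duration_s", a.duration, r.duration))
            rows.append((trial.participant, "squat_depth_m", a.depth, r.depth))
        elif label in ("sit_to_stand", "stand_to_sit"):
            a = _find_native(ar_objs, a_seg)
            r = _find_native(ref_objs, r_seg)
            rows.append((trial.participant, f"{label}_duration_s",
                         a.duration, r.duration))
    return rows


def _find_native(objs, seg):
    for o in objs:
        if o.start == seg.start and o.end == seg.end:
            return o
    raise LookupError("matched segment lost its native detector object")


def segments_to_csv(result: PipelineResult, path, rate: float = 50.0) -> None:
    df = pd.DataFrame(result.segments, columns=[
        "participant", "game", "source", "state", "start_frame", "end_frame"])
    df["start_s"] = df["start_frame"] / rate
    df["end_s"] = df["end_frame"] / rate
    df.to_csv(path, index=False)
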