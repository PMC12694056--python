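"""Between-system segment matching and classification statistics.

For each AR segment the reference segment with the highest overlap ratio
(shared frames divided by the AR segment's length) is its best match; the
match is valid when the ratio reaches 50%.  A reference segment can satisfy
only one AR segment — when several AR segments claim the same reference
segment the highest-overlap claim wins and the others count as false
positives.  True positives are matched AR segments, false positives unmatched
AR segments, false negatives unmatched reference segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segments import MotorStateSegment


@dataclass
class ClassificationReport:
    state: str
    tp: int
    fp: int
    fn: int
    precision: float | None
    recall: float | None
    f1: float | None
    mean_overlap: float | None   # fraction in [0, 1] over true positives
    overlap_sd: float | None
    matches: list = field(default_factory=list)  # (ar_seg, ref_seg, overlap)

    def to_dict(self) -> dict:
        return {
            "state": self.state, "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
            "mean_overlap": self.mean_overlap, "overlap_sd": self.overlap_sd,
            "n_ar": self.tp + self.fp, "n_ref": self.tp + self.fn,
        }


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def match_segments(ar: list[MotorStateSegment], ref: list[MotorStateSegment],
                   min_overlap: float = 0.5,
                   state: str = "") -> ClassificationReport:
    """Match same-state segment lists on a common aligned frame grid."""
    ar = sorted(ar, key=lambda s: (s.start, s.end))
    ref = sorted(ref, key=lambda s: (s.start, s.end))
    claims = []  # (overlap, ar_index, ref_index), valid claims only
    for ia, a in enumerate(ar):
        best_ov, best_ir = 0.0, None
        for ir, r in enumerate(ref):
            ov = a.intersection(r) / len(a)
            if ov > best_ov:  # strict: ties keep the earlier ref segment
                best_ov, best_ir = ov, ir
        if best_ir is not None and best_ov >= min_overlap:
            claims.append((best_ov, ia, best_ir))
    # one-to-one: highest overlap wins a contested reference segment
    claims.sort(key=lambda c: (-c[0], c[2], c[1]))
    used_ref: set[int] = set()
    used_ar: set[int] = set()
    matches = []
    for ov, ia, ir in claims:
        if ir in used_ref or ia in used_ar:
            continue
        used_ref.add(ir)
        used_ar.add(ia)
        matches.append((ar[ia], ref[ir], ov))
    matches.sort(key=lambda m: m[0].start)
    tp = len(matches)
    fp = len(ar) - tp
    fn = len(ref) - tp
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    f1 = None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    ovs = np.array([m[2] for m in matches])
    return ClassificationReport(
        state=state, tp=tp, fp=fp, fn=fn,
        precision=precision, recall=recall, f1=f1,
        mean_overlap=float(ovs.mean()) if tp else None,
        overlap_sd=float(ovs.std(ddof=1)) if tp > 1 else (0.0 if tp else None),
        matches=matches,
    )


def metric_pairs(rows) -> pd.DataFrame:
    """Per-participant paired means of per-segment metric values.

    ``rows`` is an iterable of ``(participant, metric, ar_value, ref_value)``
    tuples, one per true-positive segment (values computed on the overlapping
    frames).  Participants without any true positive for a metric simply have
    no row for it.
    """
    df = pd.DataFrame(rows, columns=["participant", "metric", "ar", "ref"])
    if df.empty:
        return df
    df = df.dropna(subset=["ar", "ref"])
    return df.groupby(["participant", "metric"], as_index=False)[["ar", "ref"]].mean()
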