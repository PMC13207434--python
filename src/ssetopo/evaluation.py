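"""Incomplete-matching evaluation protocol.

Detector errors make the stick set differ from the model SSE set, so a
complete one-to-one correspondence cannot be assumed and abstention must be
scored.  Counts are defined over predicted versus reference pairs:

* TP — predicted pairs that are reference pairs;
* FP — predicted pairs that are not (wrong correspondences);
* FN — reference pairs missed or wrongly assigned (a wrong correspondence is
  simultaneously an FP and an FN — the strictest consistent reading);
* TN — model SSEs correctly left unmatched (TN never enters the metrics).

Precision, recall and F1 are reported on a 0–100 scale:
precision = TP/(TP+FP)·100, recall = TP/(TP+FN)·100, F1 their harmonic mean,
with the degenerate conventions precision=0 when TP+FP=0, recall=0 when
TP+FN=0, F1=0 when precision+recall=0.

Also here: per-type accuracy (fractions in [0,1]), aggregation of per-protein
F1 by sequence-length group, and the paired t-test used to compare methods
across a common protein set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InputError

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "TTestResult",
    "confusion_counts",
    "precision_recall_f1",
    "evaluate_correspondence",
    "length_group_summary",
    "paired_t_test",
    "DEFAULT_LENGTH_BOUNDARIES",
]

#: Sequence-length group cut points used for benchmark aggregation;
#: intervals are closed on the left, open on the right except the last.
DEFAULT_LENGTH_BOUNDARIES = (96, 145, 228, 341, 1703)


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0
    TN: int = 0

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "FN", "TN"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative")


@dataclass
class EvalReport:
    """Full evaluation of one predicted topology against its reference."""

    counts: ConfusionCounts
    precision: float
    recall: float
    f1: float
    per_type: dict = field(default_factory=dict)
    direction_accuracy: float | None = None

    def to_dict(self) -> dict:
        return {
            "TP": self.counts.TP,
            "FP": self.counts.FP,
            "FN": self.counts.FN,
            "TN": self.counts.TN,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "per_type": dict(self.per_type),
            "direction_accuracy": self.direction_accuracy,
        }


def confusion_counts(predicted, truth) -> ConfusionCounts:
    """Count TP/FP/FN/TN for a predicted correspondence set against truth.

    Every id the prediction references must belong to the truth universe
    (its pairs plus unmatched lists); anything else signals the two files
    describe different proteins.
    """
    truth_pairs = {(s, v) for s, v, _d in truth.pairs}
    truth_sses = truth.sse_ids
    truth_sticks = truth.stick_ids

    pred_pairs = {(p.sse_id, p.stick_id) for p in predicted.pairs}
    for s, v in pred_pairs:
        if s not in truth_sses:
            raise InputError(f"predicted SSE {s!r} absent from truth universe")
        if v not in truth_sticks:
            raise InputError(f"predicted stick {v!r} absent from truth universe")
    for s in predicted.unmatched_sses:
        if s not in truth_sses:
            raise InputError(f"predicted SSE {s!r} absent from truth universe")
    for v in predicted.unmatched_sticks:
        if v not in truth_sticks:
            raise InputError(f"predicted stick {v!r} absent from truth universe")

    tp = len(pred_pairs & truth_pairs)
    fp = len(pred_pairs - truth_pairs)
    fn = len(truth_pairs) - tp
    tn = len(set(truth.unmatched_sses) & set(predicted.unmatched_sses))
    return ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn)


def precision_recall_f1(counts: ConfusionCounts):
    """Precision, recall, F1 on a 0–100 scale with total-function conventions."""
    tp, fp, fn = counts.TP, counts.FP, counts.FN
    precision = 0.0 if tp + fp == 0 else 100.0 * tp / (tp + fp)
    recall = 0.0 if tp + fn == 0 else 100.0 * tp / (tp + fn)
    f1 = (
        0.0
        if precision + recall == 0
        else 2.0 * precision * recall / (precision + recall)
    )
    return precision, recall, f1


def evaluate_correspondence(predicted, truth, sse_types=None) -> EvalReport:
    """Build the full report: counts, metrics, per-type accuracy, direction
    accuracy over the correctly matched pairs.

    ``sse_types`` maps sse_id → {'helix','strand'}; with the canonical H#/S#
    labels it can be inferred from the id prefix and may be omitted.
    """
    counts = confusion_counts(predicted, truth)
    precision, recall, f1 = precision_recall_f1(counts)

    def type_of(sse_id: str) -> str | None:
        if sse_types is not None:
            return sse_types.get(sse_id)
        if sse_id.startswith("H"):
            return "helix"
        if sse_id.startswith("S"):
            return "strand"
        return None

    truth_pairs = {(s, v): d for s, v, d in truth.pairs}
    pred_by_pair = {(p.sse_id, p.stick_id): p for p in predicted.pairs}
    correct = [pair for pair in pred_by_pair if pair in truth_pairs]

    per_type: dict = {}
    for t in ("helix", "strand"):
        total = sum(1 for (s, _v) in truth_pairs if type_of(s) == t)
        if total == 0:
            continue
        hit = sum(1 for (s, _v) in correct if type_of(s) == t)
        per_type[t] = hit / total

    direction_accuracy = None
    if correct:
        good = sum(
            1
            for pair in correct
            if pred_by_pair[pair].direction == truth_pairs[pair]
        )
        direction_accuracy = good / len(correct)

    return EvalReport(
        counts=counts,
        precision=precision,
        recall=recall,
        f1=f1,
        per_type=per_type,
        direction_accuracy=direction_accuracy,
    )


def length_group_summary(per_protein, boundaries=DEFAULT_LENGTH_BOUNDARIES):
    """Mean F1 per sequence-length group.

    ``per_protein`` is a sequence of (sequence_length, f1).  Groups are
    [b0,b1), [b1,b2), ..., [b_{k-1}, b_k] — closed on the left, open on the
    right except the last.  Empty groups are absent from the result, not
    reported as zero.
    """
    bounds = list(boundaries)
    if len(bounds) < 2 or sorted(bounds) != bounds:
        raise InputError("boundaries must be >= 2 ascending cut points")
    groups: dict = {}
    for length, f1 in per_protein:
        if length < bounds[0] or length > bounds[-1]:
            raise InputError(
                f"sequence length {length} outside [{bounds[0]}, {bounds[-1]}]"
            )
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            last = hi == bounds[-1]
            if lo <= length < hi or (last and length == hi):
                groups.setdefault((lo, hi), []).append(f1)
                break
    return {
        f"{lo}-{hi}": float(np.mean(vals)) for (lo, hi), vals in groups.items()
    }


@dataclass
class TTestResult:
    statistic: float
    pvalue: float
    status: str = "ok"  # or "zero_variance"


def paired_t_test(f1_a, f1_b) -> TTestResult:
    """Classical paired t-test on per-protein score differences.

    Two-sided p from the t distribution with n−1 degrees of freedom.  When
    the differences have zero variance the statistic is undefined and a
    distinct ``zero_variance`` status is returned (never a silent 0 or 1).
    """
    a = np.asarray(f1_a, dtype=float)
    b = np.asarray(f1_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("paired t-test needs two aligned 1-D score vectors")
    if len(a) < 2:
        raise InputError("paired t-test needs at least 2 paired scores")
    diff = a - b
    if np.ptp(diff) == 0:  # all differences identical: statistic divides by 0
        return TTestResult(statistic=float("nan"), pvalue=float("nan"),
                           status="zero_variance")
    res = stats.ttest_rel(a, b)
    return TTestResult(statistic=float(res.statistic), pvalue=float(res.pvalue))
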