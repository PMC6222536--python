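"""Binary-classification metrics from confusion counts.

Five metrics are derived from the confusion counts (TP, FP, TN, FN):
accuracy, sensitivity (recall on positives), specificity (recall on
negatives), F-score (harmonic mean of precision and sensitivity) and
Matthews correlation coefficient

    Mcc = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

Degenerate-count policy: when TP = FP = 0 (nothing was predicted positive)
the model is maximally uninformative about the positive class and Mcc is
defined as -1.  Any other vanishing denominator yields 0 for the affected
metric with a degeneracy flag recorded, so cross-validation aggregates stay
computable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

METRIC_NAMES = ("acc", "sens", "spec", "pre", "f_score", "mcc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValidationError(f"count {name} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_from_labels(y_true, y_pred) -> ConfusionCounts:
    """Confusion counts from aligned +1/-1 truth and prediction vectors."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValidationError("label vectors differ in length")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == -1) & (y_pred == 1))),
        tn=int(np.sum((y_true == -1) & (y_pred == -1))),
        fn=int(np.sum((y_true == 1) & (y_pred == -1))),
    )


@dataclass(frozen=True)
class EvaluationReport:
    """The five metrics plus precision, with the counts they came from."""

    acc: float
    sens: float
    spec: float
    pre: float
    f_score: float
    mcc: float
    counts: ConfusionCounts
    degenerate: frozenset[str] = field(default_factory=frozenset)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def metrics(counts: ConfusionCounts) -> EvaluationReport:
    """Derive the full metric report from confusion counts."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    if counts.total == 0:
        raise ValidationError("empty evaluation: all confusion counts are zero")

    degenerate: set[str] = set()

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            degenerate.add(name)
            return 0.0
        return num / den

    acc = (tp + tn) / counts.total
    sens = ratio(tp, tp + fn, "sens")
    spec = ratio(tn, tn + fp, "spec")
    pre = ratio(tp, tp + fp, "pre")
    f_score = ratio(2 * pre * sens, pre + sens, "f_score")

    if tp == 0 and fp == 0:
        mcc = -1.0  # nothing predicted positive: poorest predictive ability
    else:
        denom = math.sqrt(
            float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
        )
        if denom == 0:
            degenerate.add("mcc")
            mcc = 0.0
        else:
            mcc = (tp * tn - fp * fn) / denom

    return EvaluationReport(
        acc=acc, sens=sens, spec=spec, pre=pre, f_score=f_score, mcc=mcc,
        counts=counts, degenerate=frozenset(degenerate),
    )
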