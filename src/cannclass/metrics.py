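"""Binary-classification figures of merit: accuracy, TPR, TNR, F1, MCC.

All five follow the standard confusion-matrix definitions. MCC is defined as
0 when any factor of its denominator vanishes (the conventional limit for a
degenerate confusion matrix); TPR and TNR raise instead when their class is
absent, since reporting a rate over zero actual members is meaningless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal


class UndefinedMetricError(ValueError):
    """Raised when a rate's denominator is zero (no members of that class)."""


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not (isinstance(v, (int,)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.total < 1:
            raise ValueError("confusion matrix must count at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(truth, pred, positive) -> ConfusionMatrix:
    """Count TP/FP/TN/FN of predicted vs actual labels for one positive class."""
    truth = list(truth)
    pred = list(pred)
    if len(truth) != len(pred):
        raise ValueError(f"label vectors differ in length ({len(truth)} vs {len(pred)})")
    tp = fp = tn = fn = 0
    for t, p in zip(truth, pred):
        if t == positive:
            if p == positive:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def accuracy(cm: ConfusionMatrix) -> float:
    return (cm.tp + cm.tn) / cm.total


def tpr(cm: ConfusionMatrix) -> float:
    """Sensitivity / true positive rate: TP / (TP + FN)."""
    if cm.tp + cm.fn == 0:
        raise UndefinedMetricError("TPR undefined: no actual positives")
    return cm.tp / (cm.tp + cm.fn)


def tnr(cm: ConfusionMatrix) -> float:
    """Specificity / true negative rate: TN / (TN + FP)."""
    if cm.tn + cm.fp == 0:
        raise UndefinedMetricError("TNR undefined: no actual negatives")
    return cm.tn / (cm.tn + cm.fp)


def f1(cm: ConfusionMatrix) -> float:
    """F1 = 2TP / (2TP + FP + FN), the harmonic mean of precision and TPR."""
    denom = 2 * cm.tp + cm.fp + cm.fn
    if denom == 0:
        raise UndefinedMetricError("F1 undefined: no positives in truth or prediction")
    return 2 * cm.tp / denom


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient; 0 by convention when degenerate."""
    denom = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    if denom == 0:
        return 0.0
    return (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(denom)


def round_half_up(x: float, ndigits: int = 4) -> float:
    """Round half away from zero at ndigits decimals (report convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def all_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy/TPR/TNR/F1/MCC in one dict; undefined rates become NaN."""
    out = {"accuracy": accuracy(cm), "mcc": mcc(cm)}
    for name, fn_ in (("tpr", tpr), ("tnr", tnr), ("f1", f1)):
        try:
            out[name] = fn_(cm)
        except UndefinedMetricError:
            out[name] = float("nan")
    return out
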