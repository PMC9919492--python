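"""Confusion counts and the four classification metrics.

The positive class throughout is "walked" (the participant had at least one
qualifying walk bout inside the outcome window).  Counts are stored as floats
so that fold-averaged confusion matrices remain representable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "confusion",
    "mcc",
    "metrics_from_counts",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN for one evaluation (reals, so means of matrices fit)."""

    tp: float
    tn: float
    fp: float
    fn: float

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> float:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def positives(self) -> float:
        """Actual positives P = TP + FN."""
        return self.tp + self.fn

    @property
    def negatives(self) -> float:
        """Actual negatives N = TN + FP."""
        return self.tn + self.fp

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )

    def scaled(self, factor: float) -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp * factor, self.tn * factor, self.fp * factor, self.fn * factor
        )


@dataclass(frozen=True)
class MetricSet:
    """Accuracy, sensitivity, specificity and Matthews correlation coefficient.

    Undefined entries (zero denominator) are NaN.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "mcc": self.mcc,
        }


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Tally TP/TN/FP/FN from two equal-length binary label sequences."""
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    if not (np.isin(t, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels must be binary (0/1)")
    t = t.astype(bool)
    p = p.astype(bool)
    return ConfusionCounts(
        tp=float(np.sum(t & p)),
        tn=float(np.sum(~t & ~p)),
        fp=float(np.sum(~t & p)),
        fn=float(np.sum(t & ~p)),
    )


def mcc(cc: ConfusionCounts) -> float:
    """Matthews correlation coefficient.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

    When any marginal sum is zero the coefficient is undefined; by convention
    this returns 0.0 with a warning (a classifier that never varies carries no
    correlation signal).
    """
    marginals = (
        (cc.tp + cc.fp),
        (cc.tp + cc.fn),
        (cc.tn + cc.fp),
        (cc.tn + cc.fn),
    )
    if any(m == 0 for m in marginals):
        warnings.warn(
            "MCC undefined (zero marginal); returning 0.0 by convention",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    numerator = cc.tp * cc.tn - cc.fp * cc.fn
    return numerator / math.sqrt(math.prod(marginals))


def _ratio(num: float, den: float) -> float:
    if den == 0:
        warnings.warn(
            "metric undefined (zero denominator); returning NaN",
            RuntimeWarning,
            stacklevel=3,
        )
        return float("nan")
    return num / den


def metrics_from_counts(cc: ConfusionCounts) -> MetricSet:
    """Accuracy, sensitivity (recall on walkers), specificity and MCC."""
    if cc.total == 0:
        raise ValueError("empty confusion counts")
    return MetricSet(
        accuracy=_ratio(cc.tp + cc.tn, cc.total),
        sensitivity=_ratio(cc.tp, cc.tp + cc.fn),
        specificity=_ratio(cc.tn, cc.tn + cc.fp),
        mcc=mcc(cc),
    )
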