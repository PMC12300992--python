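"""Confusion-matrix machinery and the six classifier performance metrics.

MCC, Precision, Recall, Accuracy, Specificity, and NPV are computed directly
from their defining formulas. Zero-denominator cases return NaN (an explicit
undefined flag) rather than silently reporting 0; cross-validation summaries
exclude undefined folds with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields

import numpy as np


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        counts = (self.tp, self.tn, self.fp, self.fn)
        if any(c < 0 for c in counts):
            raise ValueError("confusion-matrix counts must be non-negative")
        if sum(counts) < 1:
            raise ValueError("confusion matrix must contain at least one instance")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    """The six evaluation metrics; NaN marks an undefined (0/0) value."""

    mcc: float
    precision: float
    recall: float
    accuracy: float
    specificity: float
    npv: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def confusion(labels, predictions) -> ConfusionMatrix:
    """Count TP/TN/FP/FN from binary label and prediction vectors (1 = active)."""
    labels = np.asarray(labels).astype(int)
    predictions = np.asarray(predictions).astype(int)
    if labels.shape != predictions.shape or labels.ndim != 1 or labels.size < 1:
        raise ValueError("labels and predictions must be equal-length 1-D, size >= 1")
    return ConfusionMatrix(
        tp=int(np.sum((labels == 1) & (predictions == 1))),
        tn=int(np.sum((labels == 0) & (predictions == 0))),
        fp=int(np.sum((labels == 0) & (predictions == 1))),
        fn=int(np.sum((labels == 1) & (predictions == 0))),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def metric_set(cm: ConfusionMatrix) -> MetricSet:
    """Compute all six metrics from a confusion matrix.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); any zero
    factor under the root makes MCC undefined (NaN).
    """
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    denom_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom_sq) if denom_sq > 0 else math.nan
    return MetricSet(
        mcc=mcc,
        precision=_ratio(tp, tp + fp),
        recall=_ratio(tp, tp + fn),
        accuracy=_ratio(tp + tn, cm.total),
        specificity=_ratio(tn, tn + fp),
        npv=_ratio(tn, tn + fn),
    )


def mcc_score(labels, predictions) -> float:
    """Convenience: MCC straight from binary vectors."""
    return metric_set(confusion(labels, predictions)).mcc


def mean_defined(scores) -> float:
    """Mean over defined (non-NaN) fold scores; warns when folds are dropped."""
    arr = np.asarray(scores, dtype=float)
    defined = arr[~np.isnan(arr)]
    if defined.size < arr.size:
        warnings.warn(
            f"{arr.size - defined.size} of {arr.size} fold scores undefined; "
            "excluded from the mean"
        )
    if defined.size == 0:
        return math.nan
    return float(defined.mean())
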