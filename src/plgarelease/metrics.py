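"""Evaluation metrics: confusion-matrix classification metrics, MAE and
Pearson r on release fractions.

Zero-denominator metrics are reported as NaN with a warning, never silently
coerced to 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ClassificationReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    matrix: ConfusionMatrix

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "tp": self.matrix.tp,
            "tn": self.matrix.tn,
            "fp": self.matrix.fp,
            "fn": self.matrix.fn,
        }


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                      RuntimeWarning, stacklevel=3)
        return float("nan")
    return num / den


def metrics_from_counts(matrix: ConfusionMatrix) -> ClassificationReport:
    """Accuracy, precision, recall and F1 from raw confusion counts."""
    tp, tn, fp, fn = matrix.tp, matrix.tn, matrix.fp, matrix.fn
    accuracy = _ratio(tp + tn, matrix.total, "accuracy")
    precision = _ratio(tp, tp + fp, "precision")
    recall = _ratio(tp, tp + fn, "recall")
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        warnings.warn("F1 undefined; reporting NaN", RuntimeWarning, stacklevel=2)
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return ClassificationReport(accuracy, precision, recall, f1, matrix)


def confusion_and_metrics(predicted, observed) -> ClassificationReport:
    """Confusion matrix and classification metrics from binary label vectors.

    The slow-release class (label 1) is the positive class.
    """
    yp = np.asarray(predicted, dtype=int)
    yt = np.asarray(observed, dtype=int)
    if yp.shape != yt.shape:
        raise ValueError("label vectors must have equal length")
    matrix = ConfusionMatrix(
        tp=int(np.sum((yp == 1) & (yt == 1))),
        tn=int(np.sum((yp == 0) & (yt == 0))),
        fp=int(np.sum((yp == 1) & (yt == 0))),
        fn=int(np.sum((yp == 0) & (yt == 1))),
    )
    return metrics_from_counts(matrix)


def mae(predicted, observed) -> float:
    """Mean absolute error between predicted and observed release fractions."""
    yp = np.asarray(predicted, dtype=float)
    yo = np.asarray(observed, dtype=float)
    if yp.size == 0 or yp.shape != yo.shape:
        raise ValueError("mae needs two equal-length, non-empty vectors")
    return float(np.mean(np.abs(yp - yo)))


def pearson_r(predicted, observed) -> float:
    """Sample Pearson correlation; NaN with a warning if either vector is
    constant (correlation undefined)."""
    yp = np.asarray(predicted, dtype=float)
    yo = np.asarray(observed, dtype=float)
    if yp.size < 2 or yp.shape != yo.shape:
        raise ValueError("pearson_r needs two equal-length vectors of length >= 2")
    if np.ptp(yp) == 0 or np.ptp(yo) == 0:
        warnings.warn("Pearson r undefined for a constant vector; reporting NaN",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(stats.pearsonr(yp, yo).statistic)
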