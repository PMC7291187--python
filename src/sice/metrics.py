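"""Scoring imputations against held-out truth.

Categorical targets are scored with confusion-matrix metrics (accuracy,
balanced accuracy, sensitivity, precision, specificity, F-measure), numeric
targets with root mean squared error.  Metrics are intended to be computed
on the artificially masked cells only — observed cells are trivially
"correct" and would inflate every score.

For multi-class targets the per-class one-vs-rest metrics are
macro-averaged (each class counts equally, regardless of prevalence);
accuracy stays the overall fraction correct.  A ratio with a zero
denominator is reported as 0 with a logged note rather than NaN.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix

__all__ = ["ConfusionMetrics", "RmseResult", "confusion_metrics", "rmse"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMetrics:
    """Confusion-matrix summary; every field is a fraction in [0, 1]."""

    n: int
    accuracy: float
    balanced_accuracy: float
    sensitivity: float
    precision: float
    specificity: float
    f_measure: float

    def as_dict(self) -> dict[str, float]:
        return {
            "n": self.n,
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "specificity": self.specificity,
            "f_measure": self.f_measure,
        }


@dataclass(frozen=True)
class RmseResult:
    """Root mean squared error over n scored cells, in target units."""

    n: int
    value: float


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.info("%s undefined (zero denominator); reporting 0", what)
        return 0.0
    return num / den


def _class_metrics(tp: int, fp: int, fn: int, tn: int) -> tuple[float, float, float, float]:
    sens = _safe_ratio(tp, tp + fn, "sensitivity")
    prec = _safe_ratio(tp, tp + fp, "precision")
    spec = _safe_ratio(tn, tn + fp, "specificity")
    f1 = _safe_ratio(2 * prec * sens, prec + sens, "F-measure")
    return sens, prec, spec, f1


def confusion_metrics(
    actual: Sequence[Any],
    predicted: Sequence[Any],
    positive: Any | None = None,
    levels: Sequence[Any] | None = None,
) -> ConfusionMetrics:
    """Score a categorical prediction against truth.

    With two classes (or ``positive`` given) the metrics come from the 2x2
    table with ``positive`` as the positive class.  With more classes each
    class is scored one-vs-rest and the metrics are macro-averaged.

    Parameters
    ----------
    actual, predicted:
        Equal-length label vectors.
    positive:
        The positive class for binary scoring.  Defaults to the first label
        in ``levels`` (or sorted order) when exactly two classes occur.
    levels:
        Optional explicit label universe and order (e.g. the schema levels);
        defaults to the sorted union of the labels present.
    """
    actual = list(actual)
    predicted = list(predicted)
    if len(actual) != len(predicted):
        raise ValueError(
            f"length mismatch: {len(actual)} actual vs {len(predicted)} predicted"
        )
    if not actual:
        raise ValueError("cannot score empty label vectors")
    if levels is None:
        universe = set(actual) | set(predicted)
        if positive is not None:
            universe.add(positive)
        levels = sorted(universe, key=str)
    levels = list(levels)
    n = len(actual)
    cm = confusion_matrix(actual, predicted, labels=levels)
    accuracy = float(np.trace(cm)) / n

    binary = len(levels) == 2 or positive is not None
    if binary:
        if positive is None:
            positive = levels[0]
        if positive not in levels:
            raise ValueError(f"positive label {positive!r} not among levels {levels}")
        i = levels.index(positive)
        tp = int(cm[i, i])
        fn = int(cm[i].sum() - tp)
        fp = int(cm[:, i].sum() - tp)
        tn = n - tp - fn - fp
        sens, prec, spec, f1 = _class_metrics(tp, fp, fn, tn)
    else:
        per = [
            _class_metrics(
                tp=int(cm[i, i]),
                fp=int(cm[:, i].sum() - cm[i, i]),
                fn=int(cm[i].sum() - cm[i, i]),
                tn=int(n - cm[i].sum() - cm[:, i].sum() + cm[i, i]),
            )
            for i in range(len(levels))
        ]
        sens, prec, spec, f1 = (float(np.mean([p[k] for p in per])) for k in range(4))

    return ConfusionMetrics(
        n=n,
        accuracy=accuracy,
        balanced_accuracy=(sens + spec) / 2,
        sensitivity=sens,
        precision=prec,
        specificity=spec,
        f_measure=f1,
    )


def rmse(actual: Sequence[float], predicted: Sequence[float]) -> RmseResult:
    """Root mean squared error: sqrt(mean((actual_i - predicted_i)^2))."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.ndim != 1:
        raise ValueError(f"shape mismatch: {a.shape} vs {p.shape}")
    if a.size == 0:
        raise ValueError("cannot score empty vectors")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(p))):
        raise ValueError("non-finite values in input")
    return RmseResult(n=int(a.size), value=float(math.sqrt(np.mean((a - p) ** 2))))
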