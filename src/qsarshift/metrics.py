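"""Binary-classification metrics from confusion counts.

A true active prediction counts as a true positive. Eight quantities are
reported: sensitivity TP/(TP+FN), specificity TN/(TN+FP), balanced
accuracy (sensitivity+specificity)/2, accuracy, positive and negative
predictive value, F-measure 2*(PPV*sensitivity)/(PPV+sensitivity), and
the Matthews correlation coefficient
(TP*TN - FP*FN)/sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN)).

Undefined ratios (zero denominator) come back as NaN, never silently 0;
the one conventional exception is the MCC, which is defined as 0 when any
factor under the root vanishes (a degenerate predictor carries no
correlation), and that substitution is logged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np

from .config import logger


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    accuracy: float
    ppv: float
    npv: float
    f_measure: float
    mcc: float
    counts: ConfusionCounts
    context: dict[str, Any] | None = None

    def to_row(self) -> dict[str, Any]:
        row = {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "balanced_accuracy": self.balanced_accuracy,
            "accuracy": self.accuracy,
            "ppv": self.ppv,
            "npv": self.npv,
            "f_measure": self.f_measure,
            "mcc": self.mcc,
            "tp": self.counts.tp,
            "tn": self.counts.tn,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
        }
        if self.context:
            row.update(self.context)
        return row


def confusion(
    labels: Sequence[int], predictions: Sequence[int]
) -> ConfusionCounts:
    """Tally confusion counts for 0/1 labels (1 = active)."""
    if len(labels) != len(predictions):
        raise ValueError(
            f"length mismatch: {len(labels)} labels vs {len(predictions)} predictions"
        )
    if len(labels) == 0:
        raise ValueError("need at least one label/prediction pair")
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if not (np.isin(y, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels and predictions must be binary 0/1")
    return ConfusionCounts(
        tp=int(((y == 1) & (p == 1)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def metric_suite(
    c: ConfusionCounts, context: dict[str, Any] | None = None
) -> MetricsReport:
    """Evaluate all eight metrics from one confusion table."""
    if c.n < 1:
        raise ValueError("metric evaluation needs at least one observation")
    tp, tn, fp, fn = float(c.tp), float(c.tn), float(c.fp), float(c.fn)

    sensitivity = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    balanced_accuracy = (sensitivity + specificity) / 2.0
    accuracy = _ratio(tp + tn, tp + fp + tn + fn)
    ppv = _ratio(tp, tp + fp)
    npv = _ratio(tn, tn + fn)
    if math.isnan(ppv) or math.isnan(sensitivity) or (ppv + sensitivity) == 0:
        f_measure = float("nan")
    else:
        f_measure = 2.0 * (ppv * sensitivity) / (ppv + sensitivity)

    denom_sq = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    if denom_sq == 0:
        logger.debug("MCC denominator zero (tp=%d tn=%d fp=%d fn=%d); using 0",
                     c.tp, c.tn, c.fp, c.fn)
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom_sq)

    return MetricsReport(
        sensitivity=sensitivity,
        specificity=specificity,
        balanced_accuracy=balanced_accuracy,
        accuracy=accuracy,
        ppv=ppv,
        npv=npv,
        f_measure=f_measure,
        mcc=mcc,
        counts=c,
        context=context,
    )


def evaluate_predictions(
    labels: Sequence[int],
    predictions: Sequence[int],
    context: dict[str, Any] | None = None,
) -> MetricsReport:
    return metric_suite(confusion(labels, predictions), context=context)
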