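"""Confusion-matrix metrics for benchmarking DEG calls against a truth set."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

__all__ = ["ConfusionCounts", "MetricReport", "confusion", "metrics"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricReport:
    precision: float
    recall: float
    fpr: float
    f1: float
    mcc: float


def confusion(
    predicted: Iterable[str], truth: Iterable[str], universe: Iterable[str]
) -> ConfusionCounts:
    """2x2 cross-tabulation of predicted vs true DEGs over a gene universe."""
    pred, tru, uni = set(predicted), set(truth), set(universe)
    if not pred <= uni:
        raise ValueError(
            f"predicted genes outside universe: {sorted(pred - uni)[:5]}"
        )
    if not tru <= uni:
        raise ValueError(f"truth genes outside universe: {sorted(tru - uni)[:5]}")
    tp = len(pred & tru)
    fp = len(pred - tru)
    fn = len(tru - pred)
    tn = len(uni) - tp - fp - fn
    return ConfusionCounts(tp, fp, tn, fn)


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("%s denominator is zero; reporting 0", name)
        return 0.0
    return num / den


def metrics(c: ConfusionCounts) -> MetricReport:
    """Precision, recall, FPR, F1 and MCC from a confusion table.

    precision = TP/(TP+FP); recall = TP/(TP+FN); FPR = FP/(FP+TN);
    F1 = 2PR/(P+R); MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    A zero denominator yields 0 with a logged warning — for MCC that is the
    random-prediction value.
    """
    precision = _ratio(c.tp, c.tp + c.fp, "precision")
    recall = _ratio(c.tp, c.tp + c.fn, "recall")
    fpr = _ratio(c.fp, c.fp + c.tn, "FPR")
    f1 = _ratio(2.0 * precision * recall, precision + recall, "F1")
    denom2 = (
        float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = _ratio(float(c.tp) * c.tn - float(c.fp) * c.fn, math.sqrt(denom2), "MCC")
    return MetricReport(precision, recall, fpr, f1, mcc)
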