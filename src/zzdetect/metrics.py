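"""Confusion-matrix evaluation for the binary healthy/affected task.

"Affected" is the positive class.  Sensitivity of the healthy class equals
the specificity of the whole dataset; both per-class sensitivities, their
miss rates, the overall accuracy OA = (TP+TN)/(TP+TN+FP+FN) and
F1 = 2TP/(2TP+FP+FN) are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import InputError, MetricError
from .postprocess import AFFECTED, HEALTHY

__all__ = [
    "ConfusionCounts",
    "confusion",
    "sensitivity",
    "miss_rate",
    "specificity",
    "overall_accuracy",
    "f1_score",
    "report",
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise InputError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(pred: Sequence[str], truth: Sequence[str]) -> ConfusionCounts:
    """Tally predictions against ground truth labels."""
    if len(pred) != len(truth):
        raise InputError("prediction and truth lists differ in length")
    c = ConfusionCounts()
    for p, t in zip(pred, truth):
        if p not in (HEALTHY, AFFECTED) or t not in (HEALTHY, AFFECTED):
            raise InputError(f"unknown label in pair ({p!r}, {t!r})")
        if t == AFFECTED:
            if p == AFFECTED:
                c.tp += 1
            else:
                c.fn += 1
        else:
            if p == HEALTHY:
                c.tn += 1
            else:
                c.fp += 1
    return c


def sensitivity(c: ConfusionCounts) -> float:
    """True positive rate TP / (TP + FN)."""
    if c.tp + c.fn == 0:
        raise MetricError("sensitivity undefined: no positive examples")
    return c.tp / (c.tp + c.fn)


def miss_rate(c: ConfusionCounts) -> float:
    """FN / (TP + FN); complement of sensitivity."""
    if c.tp + c.fn == 0:
        raise MetricError("miss rate undefined: no positive examples")
    return c.fn / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP); the healthy class's sensitivity."""
    if c.tn + c.fp == 0:
        raise MetricError("specificity undefined: no negative examples")
    return c.tn / (c.tn + c.fp)


def overall_accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise MetricError("overall accuracy undefined for empty counts")
    return (c.tp + c.tn) / c.total


def f1_score(c: ConfusionCounts) -> float:
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        raise MetricError("F1 undefined: no positive predictions or examples")
    return 2 * c.tp / denom


def report(c: ConfusionCounts) -> dict:
    """JSON-friendly summary; per-class metrics are None when undefined."""
    out = {"tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn}
    try:
        out["sensitivity_affected"] = sensitivity(c)
        out["miss_rate_affected"] = miss_rate(c)
    except MetricError:
        out["sensitivity_affected"] = out["miss_rate_affected"] = None
    try:
        out["sensitivity_healthy"] = specificity(c)
        out["miss_rate_healthy"] = 1.0 - specificity(c)
    except MetricError:
        out["sensitivity_healthy"] = out["miss_rate_healthy"] = None
    try:
        out["overall_accuracy"] = overall_accuracy(c)
    except MetricError:
        out["overall_accuracy"] = None
    try:
        out["f1"] = f1_score(c)
    except MetricError:
        out["f1"] = None
    return out
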