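"""Confusion-matrix construction and the standard binary metrics.

AD is the positive class.  With TP/FP/FN/TN counted that way:

    accuracy  = (TN + TP) / (TN + FP + FN + TP)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 TP / (2 TP + FP + FN)

A zero denominator yields an *undefined* metric (reported as ``None`` with a
reason), never a silent 0 — degenerate folds should be visible, not hidden.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import InputError


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


@dataclass
class MetricReport:
    accuracy: Optional[float]
    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]
    confusion: Optional[ConfusionMatrix]
    n: int
    undefined: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1, "n": self.n,
        }
        if self.confusion is not None:
            d["confusion"] = {"tp": self.confusion.tp, "fp": self.confusion.fp,
                              "fn": self.confusion.fn, "tn": self.confusion.tn}
        if self.undefined:
            d["undefined"] = dict(self.undefined)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def as_text(self) -> str:
        def fmt(v, reason_key):
            if v is None:
                return f"undefined ({self.undefined.get(reason_key, '?')})"
            return f"{v:.4f}"

        lines = [f"n = {self.n}"]
        if self.confusion is not None:
            c = self.confusion
            lines.append(f"confusion  TP={c.tp} FP={c.fp} FN={c.fn} TN={c.tn}")
        lines += [
            f"accuracy   {fmt(self.accuracy, 'accuracy')}",
            f"precision  {fmt(self.precision, 'precision')}",
            f"recall     {fmt(self.recall, 'recall')}",
            f"f1         {fmt(self.f1, 'f1')}",
        ]
        return "\n".join(lines)


def confusion(predictions: Sequence, truths: Sequence,
              positive_class="AD") -> ConfusionMatrix:
    """2x2 counts with the given positive class."""
    if len(predictions) != len(truths):
        raise InputError(
            f"length mismatch: {len(predictions)} predictions vs "
            f"{len(truths)} truths"
        )
    if len(predictions) == 0:
        raise InputError("cannot build a confusion matrix from zero documents")
    tp = fp = fn = tn = 0
    for pred, true in zip(predictions, truths):
        p_pos = pred == positive_class
        t_pos = true == positive_class
        if p_pos and t_pos:
            tp += 1
        elif p_pos and not t_pos:
            fp += 1
        elif not p_pos and t_pos:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def compute_metrics(cm: ConfusionMatrix) -> MetricReport:
    """Exact metric formulas from the confusion counts."""
    if cm.total == 0:
        raise InputError("all-zero confusion matrix")
    undefined: dict[str, str] = {}

    def ratio(num, den, name):
        if den == 0:
            undefined[name] = f"denominator zero ({name} undefined)"
            return None
        return num / den

    accuracy = (cm.tn + cm.tp) / cm.total
    precision = ratio(cm.tp, cm.tp + cm.fp, "precision")
    recall = ratio(cm.tp, cm.tp + cm.fn, "recall")
    f1 = ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn, "f1")
    return MetricReport(accuracy=accuracy, precision=precision, recall=recall,
                        f1=f1, confusion=cm, n=cm.total, undefined=undefined)


def evaluate(predictions: Sequence, truths: Sequence,
             positive_class="AD") -> MetricReport:
    return compute_metrics(confusion(predictions, truths, positive_class))


def mean_report(reports: Sequence[MetricReport]) -> MetricReport:
    """Unweighted mean of per-fold metrics (skipping undefined entries)."""
    if not reports:
        raise InputError("no reports to aggregate")

    def mean_of(attr):
        vals = [getattr(r, attr) for r in reports if getattr(r, attr) is not None]
        return sum(vals) / len(vals) if vals else None

    return MetricReport(
        accuracy=mean_of("accuracy"), precision=mean_of("precision"),
        recall=mean_of("recall"), f1=mean_of("f1"),
        confusion=None, n=sum(r.n for r in reports),
    )


def pooled_report(reports: Sequence[MetricReport]) -> MetricReport:
    """Metrics of the summed confusion matrix across folds."""
    mats = [r.confusion for r in reports if r.confusion is not None]
    if not mats:
        raise InputError("no confusion matrices to pool")
    total = mats[0]
    for m in mats[1:]:
        total = total + m
    return compute_metrics(total)
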