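"""Confusion-matrix bookkeeping and sensitivity/specificity/accuracy.

For each beat type H the one-vs-rest counts are read off the confusion
matrix (rows = true class, columns = predicted class): TP_H is the
diagonal cell, FN_H the rest of H's row, FP_H the rest of H's column and
TN_H everything else.  The three rates are

    SEN = TP / (TP + FN)
    SPE = TN / (TN + FP)
    ACC = (TP + TN) / (TP + TN + FP + FN)

per class, and micro-averaged by pooling the counts over classes before
dividing.  A zero denominator (e.g. a rare class absent from a test
fold) yields NaN — the explicit "undefined" marker — never an exception;
aggregation layers skip NaNs and count them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import LabelError

#: Marker for a rate whose denominator was zero.
UNDEFINED = float("nan")


def is_defined(rate: float) -> bool:
    return not math.isnan(rate)


@dataclass(frozen=True)
class ConfusionMatrix:
    """n x n counts; rows index the true class, columns the predicted."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.classes)
        if counts.shape != (n, n):
            raise ValueError(f"counts must be {n}x{n}, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def index_of(self, label: str) -> int:
        try:
            return self.classes.index(label)
        except ValueError:
            raise LabelError(
                f"label {label!r} not in classes {self.classes}"
            ) from None


@dataclass(frozen=True)
class ClassCounts:
    """One class's one-vs-rest counts (TP/TN/FP/FN)."""

    label: str
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def support(self) -> int:
        return self.tp + self.fn


@dataclass(frozen=True)
class ClassRates:
    sen: float
    spe: float
    acc: float


@dataclass(frozen=True)
class MetricsReport:
    """Per-class and micro SEN/SPE/ACC with per-class supports."""

    classes: tuple[str, ...]
    per_class: Mapping[str, ClassRates]
    micro: ClassRates
    support: Mapping[str, int]

    def to_dict(self) -> dict:
        return {
            "per_class": {
                c: {"sen": r.sen, "spe": r.spe, "acc": r.acc}
                for c, r in self.per_class.items()
            },
            "micro": {"sen": self.micro.sen, "spe": self.micro.spe,
                      "acc": self.micro.acc},
            "support": dict(self.support),
        }


def confusion(true_labels: Sequence[str], predicted_labels: Sequence[str],
              classes: Sequence[str]) -> ConfusionMatrix:
    """Tally true/predicted label pairs into an n x n matrix."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences must have equal length")
    classes = tuple(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index:
            raise LabelError(f"true label {t!r} not in classes {classes}")
        if p not in index:
            raise LabelError(f"predicted label {p!r} not in classes {classes}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(classes=classes, counts=counts)


def one_vs_rest_counts(cm: ConfusionMatrix, label: str) -> ClassCounts:
    """Partition the matrix cells into TP/FN/FP/TN for one class."""
    i = cm.index_of(label)
    tp = int(cm.counts[i, i])
    fn = int(cm.counts[i, :].sum()) - tp
    fp = int(cm.counts[:, i].sum()) - tp
    tn = cm.total - tp - fn - fp
    return ClassCounts(label=label, tp=tp, tn=tn, fp=fp, fn=fn)


def _rate(num: float, den: float) -> float:
    return num / den if den > 0 else UNDEFINED


def per_class_metrics(counts: ClassCounts) -> ClassRates:
    """SEN/SPE/ACC for one class from its own TP/TN/FP/FN."""
    return ClassRates(
        sen=_rate(counts.tp, counts.tp + counts.fn),
        spe=_rate(counts.tn, counts.tn + counts.fp),
        acc=_rate(counts.tp + counts.tn, counts.total),
    )


def micro_metrics(counts: Sequence[ClassCounts]) -> ClassRates:
    """Pooled SEN/SPE/ACC: sum TP/TN/FP/FN over classes, then divide."""
    if not counts:
        raise ValueError("need at least one ClassCounts")
    tp = sum(c.tp for c in counts)
    tn = sum(c.tn for c in counts)
    fp = sum(c.fp for c in counts)
    fn = sum(c.fn for c in counts)
    return ClassRates(
        sen=_rate(tp, tp + fn),
        spe=_rate(tn, tn + fp),
        acc=_rate(tp + tn, tp + tn + fp + fn),
    )


def report(cm: ConfusionMatrix) -> MetricsReport:
    """Full per-class + micro report for one evaluated fold."""
    counts = [one_vs_rest_counts(cm, c) for c in cm.classes]
    return MetricsReport(
        classes=cm.classes,
        per_class={c.label: per_class_metrics(c) for c in counts},
        micro=micro_metrics(counts),
        support={c.label: c.support for c in counts},
    )
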