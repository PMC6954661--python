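"""Confusion-matrix figures of merit: accuracy, sensitivity, specificity.

All values are on a 0-100 percent scale:

    accuracy    = (TP + TN) / (TP + FP + TN + FN) * 100
    sensitivity = TP / (TP + FN) * 100
    specificity = TN / (TN + FP) * 100

Multiclass datasets are handled one-vs-rest: for each class its samples are
the positives and all others the negatives, and overall accuracy is the total
correctly-classified fraction (which reduces to the binary formula for two
classes). Ratios with a zero denominator are reported as ``None``
(not-applicable) rather than 0 or 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts", "EvaluationReport",
    "confusion", "accuracy", "sensitivity", "specificity", "report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN tallies with one class treated as positive."""

    tp: int
    tn: int
    fp: int
    fn: int
    positive_class: object = None

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(y_true, y_pred, class_order: list) -> np.ndarray:
    """K x K confusion table; entry (r, c) counts true class r predicted c."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    pos = {c: i for i, c in enumerate(class_order)}
    table = np.zeros((len(class_order), len(class_order)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in pos:
            raise ValueError(f"unknown true label {t!r}")
        if p not in pos:
            raise ValueError(f"unknown predicted label {p!r}")
        table[pos[t], pos[p]] += 1
    return table


def _one_vs_rest(table: np.ndarray, k: int, positive_class=None) -> ConfusionCounts:
    tp = int(table[k, k])
    fn = int(table[k].sum() - tp)
    fp = int(table[:, k].sum() - tp)
    tn = int(table.sum() - tp - fn - fp)
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn, positive_class=positive_class)


def accuracy(cc: ConfusionCounts) -> float:
    """Percent of evaluated samples classified correctly."""
    if cc.total == 0:
        raise ValueError("accuracy undefined for zero evaluated samples")
    return 100.0 * (cc.tp + cc.tn) / cc.total


def sensitivity(cc: ConfusionCounts) -> float | None:
    """Percent of positives identified; None when no positives were evaluated."""
    if cc.tp + cc.fn == 0:
        return None
    return 100.0 * cc.tp / (cc.tp + cc.fn)


def specificity(cc: ConfusionCounts) -> float | None:
    """Percent of negatives identified; None when no negatives were evaluated."""
    if cc.tn + cc.fp == 0:
        return None
    return 100.0 * cc.tn / (cc.tn + cc.fp)


@dataclass
class EvaluationReport:
    """Overall accuracy plus per-class one-vs-rest sensitivity/specificity."""

    accuracy: float
    sensitivity: dict      # class -> percent or None
    specificity: dict      # class -> percent or None
    confusion_matrix: np.ndarray
    class_order: list

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": {str(c): v for c, v in self.sensitivity.items()},
            "specificity": {str(c): v for c, v in self.specificity.items()},
            "confusion_matrix": self.confusion_matrix.tolist(),
            "class_order": [str(c) for c in self.class_order],
        }

    def to_text(self) -> str:
        """Aligned text table: one row per class."""

        def fmt(v):
            return "n/a" if v is None else f"{v:.2f}"

        width = max(len(str(c)) for c in self.class_order)
        lines = [f"Accuracy: {self.accuracy:.2f}%",
                 f"{'Class':<{width}}  Sensitivity (%)  Specificity (%)"]
        for c in self.class_order:
            lines.append(f"{str(c):<{width}}  {fmt(self.sensitivity[c]):>15}  "
                         f"{fmt(self.specificity[c]):>15}")
        return "\n".join(lines)


def report(y_true, y_pred, class_order: list) -> EvaluationReport:
    """Full evaluation: confusion table plus per-class figures of merit."""
    table = confusion(y_true, y_pred, class_order)
    n = int(table.sum())
    if n == 0:
        raise ValueError("no samples evaluated")
    sens, spec = {}, {}
    for k, c in enumerate(class_order):
        cc = _one_vs_rest(table, k, positive_class=c)
        sens[c] = sensitivity(cc)
        spec[c] = specificity(cc)
    return EvaluationReport(
        accuracy=100.0 * float(np.trace(table)) / n,
        sensitivity=sens,
        specificity=spec,
        confusion_matrix=table,
        class_order=list(class_order),
    )
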