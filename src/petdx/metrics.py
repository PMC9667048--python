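"""Confusion-matrix performance metrics and one-vs-all ROC/AUC.

Per class the one-vs-all reduction gives TP, FP, FN, TN, from which

* specificity = TN / (TN + FP)
* precision   = TP / (TP + FP)
* sensitivity = TP / (TP + FN)
* F1          = 2 * precision * sensitivity / (precision + sensitivity)

Overall accuracy is trace / total.  Predictions outside the class set (an
"other"/inconclusive reader call) form extra confusion-matrix columns that
can never be correct but do count in the totals.  AUC uses the rank
(Mann-Whitney) formulation, with ties contributing 1/2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "per_class_metrics",
    "overall_accuracy",
    "as_percent",
    "f1_score",
    "roc_auc_one_vs_all",
]


@dataclass
class ConfusionMatrix:
    """Counts with rows = true class, columns = predicted class.

    ``pred_order`` extends ``class_order`` with any extra prediction
    categories ("other") that occurred.
    """

    counts: np.ndarray
    class_order: tuple[str, ...]
    pred_order: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.class_order), len(self.pred_order)):
            raise ValueError("counts shape does not match label orders")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    """Per-class specificity/precision/sensitivity/F1 plus overall accuracy."""

    per_class: dict[str, dict[str, float]]
    overall_accuracy: float
    auc: dict[str, float] | None = None

    def to_dict(self) -> dict:
        out: dict = {"overall_accuracy": self.overall_accuracy, "per_class": self.per_class}
        if self.auc is not None:
            out["auc"] = self.auc
        return out

    def to_table(self) -> str:
        """Results-table layout: F1, Sp, Pr, Se per class + overall accuracy."""
        lines = [f"{'class':<6} {'F1':>5} {'Sp':>4} {'Pr':>4} {'Se':>4}"]
        for cls, m in self.per_class.items():
            lines.append(
                f"{cls:<6} {m['f1']:5.2f} {as_percent(m['specificity']):4d} "
                f"{as_percent(m['precision']):4d} {as_percent(m['sensitivity']):4d}"
            )
        lines.append(f"overall accuracy: {as_percent(self.overall_accuracy)}%")
        return "\n".join(lines)


def confusion(true_labels, predicted_labels, class_order) -> ConfusionMatrix:
    """Count (true, predicted) pairs; unknown *true* labels are an error.

    Predictions outside ``class_order`` (e.g. "other") get extra columns in
    order of first appearance.
    """
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences must have equal length")
    class_order = tuple(class_order)
    known = set(class_order)
    unknown_true = [t for t in true_labels if t not in known]
    if unknown_true:
        raise ValueError(f"unknown true label(s): {sorted(set(unknown_true))}")
    extras: list[str] = []
    for p in predicted_labels:
        if p not in known and p not in extras:
            extras.append(p)
    pred_order = class_order + tuple(extras)
    counts = np.zeros((len(class_order), len(pred_order)), dtype=int)
    col = {p: j for j, p in enumerate(pred_order)}
    row = {t: i for i, t in enumerate(class_order)}
    for t, p in zip(true_labels, predicted_labels):
        counts[row[t], col[p]] += 1
    return ConfusionMatrix(counts=counts, class_order=class_order, pred_order=pred_order)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("%s undefined (0/0); reporting 0 by convention", what)
        return 0.0
    return num / den


def f1_score(precision: float, sensitivity: float) -> float:
    """Harmonic mean of precision and sensitivity (0 when both are 0)."""
    if precision + sensitivity == 0:
        return 0.0
    return 2.0 * precision * sensitivity / (precision + sensitivity)


def per_class_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-all metrics per class plus overall accuracy.

    For class *i*: TP is the diagonal cell, FN the rest of its row
    (including any "other" predictions), FP the rest of its column, and TN
    everything else.  Divisions by zero yield 0 with a logged warning.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    per_class: dict[str, dict[str, float]] = {}
    total = cm.total
    diag = 0
    for i, cls in enumerate(cm.class_order):
        j = cm.pred_order.index(cls)
        tp = int(cm.counts[i, j])
        fn = int(cm.counts[i, :].sum()) - tp
        fp = int(cm.counts[:, j].sum()) - tp
        tn = total - tp - fn - fp
        precision = _safe_div(tp, tp + fp, f"precision[{cls}]")
        sensitivity = _safe_div(tp, tp + fn, f"sensitivity[{cls}]")
        specificity = _safe_div(tn, tn + fp, f"specificity[{cls}]")
        per_class[cls] = {
            "specificity": specificity,
            "precision": precision,
            "sensitivity": sensitivity,
            "f1": f1_score(precision, sensitivity),
        }
        diag += tp
    return MetricsReport(per_class=per_class, overall_accuracy=diag / total)


def overall_accuracy(correct: int, total: int) -> float:
    """Proportion of correctly classified cases."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= correct <= total:
        raise ValueError("need 0 <= correct <= total")
    return correct / total


def as_percent(proportion: float) -> int:
    """Integer percent, rounding half away from zero (0.785 -> 79)."""
    return int(math.floor(abs(proportion) * 100.0 + 0.5)) * (
        -1 if proportion < 0 else 1
    )


def roc_auc_one_vs_all(class_scores, true_labels, cls) -> float:
    """AUC for class-vs-rest by the rank (Mann-Whitney) formulation.

    ``class_scores`` are the per-subject scores for ``cls`` (here: vote
    fractions from the ensemble); tied scores contribute 1/2.
    """
    scores = np.asarray(class_scores, dtype=float)
    truth = np.asarray(list(true_labels))
    if scores.shape[0] != truth.shape[0]:
        raise ValueError("scores and labels must align")
    pos = truth == cls
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0:
        raise ValueError(f"class {cls!r} absent from the true labels")
    if n_neg == 0:
        raise ValueError(f"class {cls!r} is the only class present")
    ranks = rankdata(scores)  # average ranks handle ties -> 1/2 per tied pair
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))
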