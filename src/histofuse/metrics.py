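"""The Kimia Path24 accuracy protocol and per-class reporting.

Three summary scores over a K-class confusion matrix C, where C[s, t]
counts test patches of true class s assigned to class t:

* patch-to-scan accuracy  eta_p  = trace(C) / n_tot          (micro accuracy)
* whole-scan accuracy     eta_w  = mean_s C[s, s] / n_Gamma_s (macro recall,
  averaged over the classes with nonzero test support)
* total accuracy          eta_total = eta_p * eta_w

eta_total is always the product of the *unrounded* factors; only the
rendered tables round (percentages to 2 decimals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import ClassLabel, make_labels

logger = logging.getLogger("histofuse")


@dataclass
class PredictionSet:
    """Per-patch predicted labels aligned with a test set's true labels.

    The per-class retrieved set R (patches the classifier assigned to a
    class) is implicit: R for class t is ``{i : predicted[i] == t}``.
    """

    predicted: np.ndarray
    truth: np.ndarray
    num_classes: int

    def __post_init__(self):
        self.predicted = np.asarray(self.predicted, dtype=np.int64)
        self.truth = np.asarray(self.truth, dtype=np.int64)
        if self.predicted.shape != self.truth.shape:
            raise ValueError("one prediction per patch required")

    def retrieved(self, class_index: int) -> np.ndarray:
        """Indices of patches assigned to ``class_index`` (the set R)."""
        return np.flatnonzero(self.predicted == class_index)


def confusion_matrix(truth: Sequence[int], pred: Sequence[int],
                     num_classes: int) -> np.ndarray:
    """K x K count matrix: entry (s, t) = patches of class s predicted t."""
    truth = np.asarray(truth, dtype=np.int64)
    pred = np.asarray(pred, dtype=np.int64)
    if truth.shape != pred.shape or truth.ndim != 1:
        raise ValueError("truth and pred must be 1-D sequences of equal length")
    for name, arr in (("truth", truth), ("pred", pred)):
        if arr.size and (arr.min() < 0 or arr.max() >= num_classes):
            raise ValueError(f"{name} labels outside [0, {num_classes - 1}]")
    mat = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(mat, (truth, pred), 1)
    return mat


def _check_confusion(confusion: np.ndarray) -> np.ndarray:
    confusion = np.asarray(confusion)
    if confusion.ndim != 2 or confusion.shape[0] != confusion.shape[1]:
        raise ValueError("confusion matrix must be square")
    if confusion.size == 0:
        raise ValueError("confusion matrix is empty")
    if (confusion < 0).any():
        raise ValueError("confusion matrix has negative counts")
    return confusion.astype(np.int64)


def patch_to_scan_accuracy(confusion: np.ndarray) -> float:
    """eta_p: fraction of all test patches assigned to their true class."""
    confusion = _check_confusion(confusion)
    total = int(confusion.sum())
    if total == 0:
        raise ValueError("confusion matrix has zero total count")
    return float(np.trace(confusion)) / total


def whole_scan_accuracy(confusion: np.ndarray) -> float:
    """eta_w: unweighted mean of per-class recalls.

    Classes with zero test support contribute no recall; they are excluded
    from the mean with a warning, so the 1/K factor generalizes to 1/K'
    over the K' supported classes (and reduces to 1/24 on the full 24-class
    test layout).
    """
    confusion = _check_confusion(confusion)
    support = confusion.sum(axis=1)
    included = support > 0
    if not included.any():
        raise ValueError("every class has zero test support")
    if not included.all():
        skipped = np.flatnonzero(~included)
        logger.warning(
            "whole_scan_accuracy: excluding %d class(es) with zero test "
            "support: %s", skipped.size, [f"c{i}" for i in skipped]
        )
    recalls = np.diag(confusion)[included] / support[included]
    return float(recalls.mean())


def total_accuracy(eta_p: float, eta_w: float) -> float:
    """eta_total = eta_p * eta_w (always from unrounded factors)."""
    for name, v in (("eta_p", eta_p), ("eta_w", eta_w)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return eta_p * eta_w


def per_class_report(confusion: np.ndarray) -> pd.DataFrame:
    """Support, precision, recall and F1 per class, unrounded.

    Zero-denominator conventions: precision is 0 when nothing was assigned
    to the class, recall is 0 when the class has no test patches, F1 is 0
    when precision + recall is 0.
    """
    confusion = _check_confusion(confusion)
    tp = np.diag(confusion).astype(np.float64)
    support = confusion.sum(axis=1)
    assigned = confusion.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(assigned > 0, tp / np.maximum(assigned, 1), 0.0)
        recall = np.where(support > 0, tp / np.maximum(support, 1), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.maximum(denom, 1e-300), 0.0)
    return pd.DataFrame(
        {
            "class": [f"c{i}" for i in range(confusion.shape[0])],
            "support": support,
            "precision": precision,
            "recall": recall,
            "f1": f1,
        }
    )


@dataclass
class EvaluationReport:
    """The three protocol scores plus the per-class table for one model."""

    eta_p: float
    eta_w: float
    eta_total: float
    confusion: np.ndarray
    per_class: pd.DataFrame = field(repr=False)

    @classmethod
    def from_confusion(cls, confusion: np.ndarray) -> "EvaluationReport":
        eta_p = patch_to_scan_accuracy(confusion)
        eta_w = whole_scan_accuracy(confusion)
        return cls(
            eta_p=eta_p,
            eta_w=eta_w,
            eta_total=total_accuracy(eta_p, eta_w),
            confusion=_check_confusion(confusion),
            per_class=per_class_report(confusion),
        )

    @classmethod
    def from_predictions(cls, truth: Sequence[int], pred: Sequence[int],
                         num_classes: int) -> "EvaluationReport":
        return cls.from_confusion(confusion_matrix(truth, pred, num_classes))

    def summary_row(self) -> dict[str, float]:
        """Percentages to 2 decimals, comparison-table style."""
        return {
            "eta_p_pct": round(100.0 * self.eta_p, 2),
            "eta_w_pct": round(100.0 * self.eta_w, 2),
            "eta_total_pct": round(100.0 * self.eta_total, 2),
        }


# ---------------------------------------------------------------------------
# renderers


def render_per_class_table(report: pd.DataFrame) -> str:
    """Aligned plain-text per-class table, fractions to 2 decimals."""
    shown = report.copy()
    for col in ("precision", "recall", "f1"):
        shown[col] = shown[col].map(lambda v: f"{v:.2f}")
    return shown.to_string(index=False)


def per_class_to_csv(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, index=False, float_format="%.10f")


def confusion_to_csv(confusion: np.ndarray, path: str | Path) -> None:
    confusion = _check_confusion(confusion)
    labels = [c.name for c in make_labels(confusion.shape[0])]
    pd.DataFrame(confusion, index=labels, columns=labels).to_csv(path)


def comparison_table(
    reports: Sequence[tuple[str, EvaluationReport]]
) -> pd.DataFrame:
    """One row per named report with eta_p / eta_w / eta_total percentages."""
    reports = list(reports)
    if not reports:
        raise ValueError("comparison_table needs at least one report")
    names = [name for name, _ in reports]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate report names: {dup}")
    rows = [{"model": name, **rep.summary_row()} for name, rep in reports]
    return pd.DataFrame(rows)


def render_comparison_table(table: pd.DataFrame) -> str:
    shown = table.copy()
    for col in ("eta_p_pct", "eta_w_pct", "eta_total_pct"):
        shown[col] = shown[col].map(lambda v: f"{v:.2f}")
    return shown.to_string(index=False)
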