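"""Grouped stratified cross-validation and slide-level performance metrics.

Accuracy, sensitivity and specificity follow the standard confusion-matrix
formulas and are reported as percentages; ROC/AUC uses the trapezoidal rule
over the empirical curve with the fused slide score H_i / M_i.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Metrics",
    "EvalReport",
    "grouped_stratified_kfold",
    "confusion_counts",
    "performance_metrics",
    "counts_from_rates",
    "roc_auc",
]

MALIGNANT = 1
BENIGN = -1


@dataclass(frozen=True)
class Metrics:
    """Percent-scale rates; a rate with a zero denominator is None and flagged."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    undefined: tuple[str, ...] = ()

    def rounded(self, ndigits: int = 1) -> "Metrics":
        rnd = lambda v: None if v is None else round(v, ndigits)
        return Metrics(
            accuracy=rnd(self.accuracy),
            sensitivity=rnd(self.sensitivity),
            specificity=rnd(self.specificity),
            undefined=self.undefined,
        )


@dataclass
class EvalReport:
    """Slide-level evaluation: confusion counts, rates, ROC and fold detail."""

    tp: int
    tn: int
    fp: int
    fn: int
    metrics: Metrics
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    auc: float | None = None
    folds: list[dict] = field(default_factory=list)

    @property
    def n_slides(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = asdict(self)
        payload["metrics"] = asdict(self.metrics)
        path.write_text(json.dumps(payload, indent=2, default=float))
        return path


def grouped_stratified_kfold(labels, groups, k: int = 5, seed: int = 0) -> np.ndarray:
    """Assign each slide to one of ``k`` folds, keeping patients intact.

    All slides of one patient land in a single fold, and fold class
    proportions approximate the global proportions where feasible.  Returns a
    fold index per slide.
    """
    from sklearn.model_selection import StratifiedGroupKFold

    labels = np.asarray(labels)
    groups = np.asarray(groups)
    if labels.shape != groups.shape:
        raise ValueError("labels and groups must align")
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    n_groups = len(np.unique(groups))
    if n_groups < k:
        raise ValueError(f"need at least {k} patients for {k} folds, got {n_groups}")

    splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.full(len(labels), -1, dtype=int)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(len(labels)), labels, groups)):
        assignment[test_idx] = fold
    if np.any(assignment < 0):
        raise RuntimeError("fold assignment left slides unassigned")
    for group in np.unique(groups):
        if len(np.unique(assignment[groups == group])) != 1:
            raise RuntimeError(f"patient {group} straddles folds")
    return assignment


def confusion_counts(y_true, y_pred) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) with +1 as the positive (malignant) class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must align")
    tp = int(np.sum((y_true == MALIGNANT) & (y_pred == MALIGNANT)))
    tn = int(np.sum((y_true == BENIGN) & (y_pred == BENIGN)))
    fp = int(np.sum((y_true == BENIGN) & (y_pred == MALIGNANT)))
    fn = int(np.sum((y_true == MALIGNANT) & (y_pred == BENIGN)))
    return tp, tn, fp, fn


def performance_metrics(tp: int, tn: int, fp: int, fn: int) -> Metrics:
    """Accuracy, sensitivity, specificity as percentages.

    accuracy = (TP+TN)/(TP+TN+FP+FN); sensitivity = TP/(TP+FN);
    specificity = TN/(TN+FP).  A zero denominator flags the rate as
    undefined rather than silently reporting zero.
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    undefined = []

    def rate(num: int, den: int, name: str) -> float | None:
        if den == 0:
            undefined.append(name)
            return None
        return 100.0 * num / den

    accuracy = rate(tp + tn, tp + tn + fp + fn, "accuracy")
    sensitivity = rate(tp, tp + fn, "sensitivity")
    specificity = rate(tn, tn + fp, "specificity")
    return Metrics(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        undefined=tuple(undefined),
    )


def counts_from_rates(
    sensitivity_pct: float, specificity_pct: float, n_pos: int, n_neg: int
) -> tuple[int, int, int, int]:
    """Reconstruct integer (TP, TN, FP, FN) from percent rates and class sizes."""
    if n_pos < 0 or n_neg < 0:
        raise ValueError("class sizes must be non-negative")
    tp = int(round(sensitivity_pct / 100.0 * n_pos))
    tn = int(round(specificity_pct / 100.0 * n_neg))
    return tp, tn, n_neg - tn, n_pos - tp


def roc_auc(scores, labels) -> tuple[list[tuple[float, float]], float]:
    """Empirical ROC points (FPR, TPR) and trapezoidal AUC.

    Requires both classes present; slide scores are typically H_i / M_i.
    """
    from sklearn.metrics import roc_curve

    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    classes = set(np.unique(labels))
    if classes != {MALIGNANT, BENIGN}:
        raise ValueError(f"both classes (+1/-1) must be present, got {sorted(classes)}")
    fpr, tpr, _ = roc_curve(labels, scores, pos_label=MALIGNANT)
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc
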