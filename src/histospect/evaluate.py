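"""Validation metrics: confusion matrices, per-class counts, one-vs-rest
accuracy/sensitivity/specificity/precision/F1, macro summaries and ROC/AUC.

Per class ``i`` the one-vs-rest counts are read off the confusion matrix
(``TP = cm[i,i]``, ``FN`` the rest of row ``i``, ``FP`` the rest of column
``i``, ``TN`` everything else) and the five standard metrics follow:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)            (recall)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)
    F1          = 2 TP / (2 TP + FP + FN)

Note the one-vs-rest per-class accuracy is a different quantity from the
overall accuracy ``trace(cm) / n``; both are reported separately.  A 0/0
denominator yields 0 with a logged warning.  Macro summaries are the
arithmetic mean and *population* standard deviation across classes.  AUC is
computed per class one-vs-rest by the mid-rank (Mann-Whitney) method, which
equals the pairwise concordance count with ties scored one half.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ConfusionMatrix", "ClassCounts", "ClassMetrics", "EvaluationReport",
    "confusion_matrix", "class_counts", "metrics_from_counts",
    "macro_summary", "roc_auc_ovr", "roc_points", "evaluate_predictions",
]

_METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "f1")


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # rows = true class, cols = predicted class
    class_names: list[str]

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def overall_accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.n

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.counts, index=self.class_names,
                     columns=self.class_names).to_csv(path)


@dataclass
class ClassCounts:
    TP: int
    TN: int
    FP: int
    FN: int


@dataclass
class ClassMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float


def confusion_matrix(y_true, y_pred, class_names: list[str]) -> ConfusionMatrix:
    """Count ``cm[i, j] = #{true i predicted j}`` over the class set."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size == 0:
        raise ValueError("empty predictions")
    G = len(class_names)
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if arr.min() < 0 or arr.max() >= G:
            raise ValueError(f"{name} holds labels outside [0, {G})")
    counts = np.zeros((G, G), dtype=int)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts, list(class_names))


def class_counts(cm: ConfusionMatrix, class_index: int) -> ClassCounts:
    """One-vs-rest TP/TN/FP/FN for one class."""
    G = cm.counts.shape[0]
    if not 0 <= class_index < G:
        raise IndexError(f"class index {class_index} out of range [0, {G})")
    tp = int(cm.counts[class_index, class_index])
    fn = int(cm.counts[class_index].sum()) - tp
    fp = int(cm.counts[:, class_index].sum()) - tp
    tn = cm.n - tp - fn - fp
    return ClassCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: 0/0 denominator, reporting 0", RuntimeWarning,
                      stacklevel=3)
        return 0.0
    return num / den


def metrics_from_counts(c: ClassCounts) -> ClassMetrics:
    """The five one-vs-rest metrics for a single class."""
    total = c.TP + c.TN + c.FP + c.FN
    if total == 0:
        raise ValueError("all counts are zero")
    return ClassMetrics(
        accuracy=(c.TP + c.TN) / total,
        sensitivity=_ratio(c.TP, c.TP + c.FN, "sensitivity"),
        specificity=_ratio(c.TN, c.TN + c.FP, "specificity"),
        precision=_ratio(c.TP, c.TP + c.FP, "precision"),
        f1=_ratio(2 * c.TP, 2 * c.TP + c.FP + c.FN, "f1"),
    )


def macro_summary(per_class: list[ClassMetrics]) -> dict[str, dict[str, float]]:
    """Mean and population SD of each metric across classes."""
    if not per_class:
        raise ValueError("no per-class metrics")
    out: dict[str, dict[str, float]] = {}
    for name in _METRIC_NAMES:
        vals = np.array([getattr(m, name) for m in per_class])
        out[name] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=0))}
    return out


def roc_auc_ovr(y_true, scores) -> list[float | None]:
    """Per-class one-vs-rest AUC by mid-rank; ``None`` for absent classes."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] != y_true.shape[0]:
        raise ValueError("scores must be (n_samples, n_classes)")
    aucs: list[float | None] = []
    for k in range(scores.shape[1]):
        pos = y_true == k
        n_pos = int(pos.sum())
        n_neg = y_true.shape[0] - n_pos
        if n_pos == 0 or n_neg == 0:
            aucs.append(None)
            continue
        ranks = rankdata(scores[:, k])  # mid-ranks for ties
        auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        aucs.append(float(auc))
    return aucs


def roc_points(y_true, score, positive_class: int) -> np.ndarray:
    """One-vs-rest ROC curve points ``(fpr, tpr)`` sorted by threshold."""
    y_true = np.asarray(y_true, dtype=int)
    score = np.asarray(score, dtype=float)
    pos = y_true == positive_class
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both positive and negative samples")
    order = np.argsort(-score, kind="stable")
    tp = np.cumsum(pos[order])
    fp = np.cumsum(~pos[order])
    # collapse tied thresholds to their last point
    keep = np.append(np.diff(score[order]) != 0, True)
    pts = np.column_stack([fp[keep] / n_neg, tp[keep] / n_pos])
    return np.vstack([[0.0, 0.0], pts])


@dataclass
class EvaluationReport:
    """Everything measured on one test partition."""

    class_names: list[str]
    confusion: ConfusionMatrix
    per_class_counts: list[ClassCounts]
    per_class_metrics: list[ClassMetrics]
    macro: dict[str, dict[str, float]]
    overall_accuracy: float
    auc: list[float | None]

    def to_dict(self) -> dict:
        return {
            "class_names": self.class_names,
            "confusion_matrix": self.confusion.counts.tolist(),
            "per_class_counts": [asdict(c) for c in self.per_class_counts],
            "per_class_metrics": [asdict(m) for m in self.per_class_metrics],
            "macro": self.macro,
            "overall_accuracy": self.overall_accuracy,
            "auc_one_vs_rest": self.auc,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def evaluate_predictions(y_true, y_pred, class_names: list[str],
                         scores=None) -> EvaluationReport:
    """Assemble the full report from predictions (and scores, for AUC)."""
    cm = confusion_matrix(y_true, y_pred, class_names)
    counts = [class_counts(cm, i) for i in range(len(class_names))]
    metrics = [metrics_from_counts(c) for c in counts]
    auc: list[float | None] = [None] * len(class_names)
    if scores is not None:
        auc = roc_auc_ovr(y_true, scores)
    return EvaluationReport(
        class_names=list(class_names),
        confusion=cm,
        per_class_counts=counts,
        per_class_metrics=metrics,
        macro=macro_summary(metrics),
        overall_accuracy=cm.overall_accuracy(),
        auc=auc,
    )
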