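"""Accuracy, per-class precision/recall/F1, ROC/AUC and confusion matrices.

All per-class metrics are one-vs-rest with the zero-denominator
convention (an undefined precision, recall or F1 is reported as 0).  For
the binary tasks the positive class is label 2 ("error present" /
"error over 3 mm").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve

from .classifiers import PredictionResult

POSITIVE_CLASS = 2


@dataclass
class ConfusionMatrix:
    """n x n count matrix; rows are true classes, columns predicted."""

    counts: np.ndarray
    classes: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.classes = np.asarray(self.classes)
        n = len(self.classes)
        if self.counts.shape != (n, n):
            raise ValueError("counts must be square and match the class list")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, cls) -> tuple[int, int, int, int]:
        """(TP, TN, FP, FN) counts for one class against the rest."""
        k = int(np.flatnonzero(self.classes == cls)[0])
        tp = int(self.counts[k, k])
        fp = int(self.counts[:, k].sum() - tp)
        fn = int(self.counts[k, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return tp, tn, fp, fn

    def normalized(self) -> np.ndarray:
        """Row-normalized view (per-true-class recall fractions)."""
        rows = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.counts / rows
        return np.nan_to_num(out)


def accuracy(result: PredictionResult) -> float:
    """Fraction of correct predictions, (TP + TN) / total."""
    if len(result.y_true) == 0:
        raise ValueError("cannot score an empty prediction set")
    return float(np.mean(result.y_true == result.y_pred))


def confusion(result: PredictionResult) -> ConfusionMatrix:
    classes = np.asarray(result.classes)
    counts = _sk_confusion(result.y_true, result.y_pred, labels=classes)
    return ConfusionMatrix(counts=counts, classes=classes)


def precision_recall_f1(cm: ConfusionMatrix, cls) -> tuple[float, float, float]:
    """One-vs-rest precision TP/(TP+FP), recall TP/(TP+FN) and F1.

    F1 is the harmonic mean 2PR/(P+R); any zero denominator yields 0.
    """
    tp, _tn, fp, fn = cm.one_vs_rest(cls)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return precision, recall, f1


def roc_auc(
    result: PredictionResult, positive_class=POSITIVE_CLASS
) -> tuple[np.ndarray, float]:
    """ROC curve points and trapezoidal AUC for a binary task.

    Equals the Mann-Whitney concordance probability of the positive-class
    scores.  Returns ``(curve, auc)`` where ``curve`` is an (n, 2) array
    of (FPR, TPR) points.
    """
    classes = list(result.classes)
    if positive_class not in classes:
        raise ValueError(f"class {positive_class!r} not in {classes}")
    truth = result.y_true == positive_class
    if truth.all() or not truth.any():
        raise ValueError("ROC needs both classes present in the truth")
    scores = result.scores[:, classes.index(positive_class)]
    fpr, tpr, _ = _sk_roc_curve(truth.astype(int), scores)
    return np.column_stack([fpr, tpr]), float(_trapezoid_auc(fpr, tpr))


def plot_confusion(cm: ConfusionMatrix, path, title: str = "") -> None:
    """Write a confusion-matrix heatmap (counts annotated) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.imshow(cm.normalized(), cmap="Blues", vmin=0, vmax=1)
    n = len(cm.classes)
    for i in range(n):
        for j in range(n):
            ax.text(j, i, str(cm.counts[i, j]), ha="center", va="center",
                    fontsize=8)
    ax.set_xticks(range(n), [str(c) for c in cm.classes])
    ax.set_yticks(range(n), [str(c) for c in cm.classes])
    ax.set_xlabel("predicted label")
    ax.set_ylabel("true label")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_roc(curves: list[tuple[str, np.ndarray, float]], path,
             title: str = "") -> None:
    """Write ROC curves (label, (FPR, TPR) points, AUC) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    for label, curve, auc_value in curves:
        ax.plot(curve[:, 0], curve[:, 1], label=f"{label} (AUC {auc_value:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def summarize(result: PredictionResult) -> dict:
    """Flat metric bundle for one prediction result (JSON-friendly)."""
    cm = confusion(result)
    out = {
        "task": result.task,
        "ml_config": result.ml_config,
        "model": result.model_kind,
        "n_test": len(result.y_true),
        "accuracy": accuracy(result),
        "confusion": cm.counts.tolist(),
        "classes": np.asarray(cm.classes).tolist(),
        "per_class": {
            str(c): dict(
                zip(("precision", "recall", "f1"), precision_recall_f1(cm, c))
            )
            for c in cm.classes
        },
        "hyperparameters": getattr(result, "selected_params", {}),
    }
    if len(cm.classes) == 2:
        try:
            _, value = roc_auc(result)
            out["auc"] = value
        except ValueError:
            out["auc"] = None
    return out
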