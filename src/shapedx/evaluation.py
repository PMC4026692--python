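"""Evaluation of multi-class and pairwise classification runs.

The headline quantity is the size-weighted mean of the three one-vs-rest
ROC AUCs in the three-class test (w_i = n_i / Σ n_j over test-set class
sizes).  Misclassification structure is summarized by the confusion matrix
and its "cobweb" representation: one radar axis per ordered off-diagonal
entry (six axes for three classes), each a row-normalized misclassification
rate in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score

__all__ = [
    "EvaluationReport",
    "weighted_multiclass_auc",
    "confusion_and_cobweb",
    "binary_metrics",
    "evaluate_multiclass",
    "render_cobweb",
]


@dataclass
class EvaluationReport:
    """Container for one evaluation run (multi-class or pairwise)."""

    per_class_auc: dict[str, float]
    weights: dict[str, float]
    weighted_auc: float
    confusion: pd.DataFrame
    cobweb_axes: list[tuple[str, float]]
    binary: dict[str, float] | None = None  # AUC/sensitivity/specificity for 2-class

    def to_dict(self) -> dict:
        out = {
            "per_class_auc": self.per_class_auc,
            "weights": self.weights,
            "weighted_auc": self.weighted_auc,
            "confusion_counts": self.confusion.to_dict(),
            "cobweb_axes": {k: v for k, v in self.cobweb_axes},
        }
        if self.binary is not None:
            out["binary"] = self.binary
        return out


def weighted_multiclass_auc(
    scores: pd.DataFrame, y_true: np.ndarray | pd.Series
) -> tuple[dict[str, float], dict[str, float], float]:
    """One-vs-rest AUC per class and their test-size-weighted mean.

    ``scores`` columns are class names; per class c the ROC uses score_c with
    c-vs-rest labels (Mann–Whitney estimator, ties get half credit).  Classes
    absent from the test set are excluded and the weights renormalized.
    """
    y = np.asarray(y_true)
    present = [c for c in scores.columns if (y == c).any()]
    absent = [c for c in scores.columns if c not in present]
    if absent:
        warnings.warn(
            f"class(es) absent from test set excluded from AUC: {absent}",
            stacklevel=2,
        )
    aucs, weights = {}, {}
    n_total = sum(int((y == c).sum()) for c in present)
    for c in present:
        pos = (y == c).astype(int)
        if pos.all():
            raise ValueError(f"class {c!r} has no negative examples")
        aucs[c] = float(roc_auc_score(pos, scores[c].to_numpy()))
        weights[c] = int((y == c).sum()) / n_total
    weighted = float(sum(weights[c] * aucs[c] for c in present))
    return aucs, weights, weighted


def confusion_and_cobweb(
    y_true: np.ndarray | pd.Series,
    y_pred: np.ndarray | pd.Series,
    classes: list[str] | None = None,
) -> tuple[pd.DataFrame, list[tuple[str, float]]]:
    """K×K confusion counts plus the K(K−1) ordered misclassification axes.

    Axis "A → B" carries the row-normalized rate of true-A subjects predicted
    B; for three classes exactly six axes.  Rows with no test subjects yield
    rate 0.
    """
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    unseen = set(y_pred) - set(classes)
    if unseen:
        raise ValueError(f"unseen predicted label(s): {sorted(unseen)}")
    counts = _sk_confusion(y_true, y_pred, labels=classes)
    confusion = pd.DataFrame(counts, index=classes, columns=classes)
    axes = []
    for i, a in enumerate(classes):
        row_n = counts[i].sum()
        for j, b in enumerate(classes):
            if i == j:
                continue
            rate = counts[i, j] / row_n if row_n else 0.0
            axes.append((f"{a} → {b}", float(rate)))
    return confusion, axes


def binary_metrics(
    scores: pd.DataFrame, y_true: np.ndarray | pd.Series, positive: str
) -> dict[str, float]:
    """AUC plus sensitivity/specificity at the argmax (coupled-score) decision."""
    y = np.asarray(y_true)
    classes = list(scores.columns)
    if positive not in classes:
        raise ValueError(f"positive class {positive!r} not in score columns")
    pos_mask = y == positive
    if pos_mask.all() or not pos_mask.any():
        raise ValueError("both classes must be present in the test set")
    auc = float(roc_auc_score(pos_mask.astype(int), scores[positive].to_numpy()))
    pred = scores.columns[np.argmax(scores.to_numpy(), axis=1)]
    pred_pos = np.asarray(pred) == positive
    tp = int((pred_pos & pos_mask).sum())
    fn = int((~pred_pos & pos_mask).sum())
    tn = int((~pred_pos & ~pos_mask).sum())
    fp = int((pred_pos & ~pos_mask).sum())
    return {
        "auc": auc,
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
    }


def evaluate_multiclass(
    scores: pd.DataFrame, y_true: np.ndarray | pd.Series
) -> EvaluationReport:
    """Full report: per-class/weighted AUC, confusion counts, cobweb axes."""
    y = np.asarray(y_true)
    aucs, weights, weighted = weighted_multiclass_auc(scores, y)
    pred = np.asarray(scores.columns[np.argmax(scores.to_numpy(), axis=1)])
    confusion, axes = confusion_and_cobweb(y, pred, classes=list(scores.columns))
    binary = None
    if len(scores.columns) == 2:
        binary = binary_metrics(scores, y, positive=str(scores.columns[0]))
    return EvaluationReport(
        per_class_auc=aucs,
        weights=weights,
        weighted_auc=weighted,
        confusion=confusion,
        cobweb_axes=axes,
        binary=binary,
    )


def render_cobweb(
    axes_by_set: dict[str, dict[str, float]], path: str
) -> None:
    """Radar-style plot of misclassification rates, one polygon per feature set.

    Axes run from 0 at the center to 1 at the rim.  Rates outside [0, 1] are
    clipped with a warning.
    """
    from matplotlib.figure import Figure

    first = next(iter(axes_by_set.values()))
    axis_names = list(first.keys())
    if len(axis_names) < 3:
        raise ValueError("cobweb plot needs >= 3 axes")
    angles = np.linspace(0, 2 * np.pi, len(axis_names), endpoint=False)
    fig = Figure(figsize=(6, 6))
    ax = fig.add_subplot(projection="polar")
    for name, rates in axes_by_set.items():
        vals = np.array([rates[a] for a in axis_names], dtype=float)
        if (vals < 0).any() or (vals > 1).any():
            warnings.warn(f"rates for {name!r} clipped to [0, 1]", stacklevel=2)
            vals = np.clip(vals, 0, 1)
        closed = np.append(vals, vals[0])
        ax.plot(np.append(angles, angles[0]), closed, label=name)
        ax.fill(np.append(angles, angles[0]), closed, alpha=0.1)
    ax.set_xticks(angles)
    ax.set_xticklabels(axis_names, fontsize=8)
    ax.set_ylim(0, 1)
    ax.legend(loc="upper right", bbox_to_anchor=(1.3, 1.1), fontsize=8)
    fig.savefig(path, bbox_inches="tight", dpi=150)
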