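"""Stratified k-fold cross-validation and the metric suite.

Per test fold the suite reports sensitivity (recall), specificity,
precision, F1, accuracy and AUC, then summarises each metric as
mean +/- SD across folds.  AUC is computed as the Mann-Whitney pair
statistic (probability a random positive outranks a random negative, ties
counted half), which equals the trapezoidal area under the empirical ROC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from drscreen.exceptions import UndefinedStatisticError

__all__ = [
    "FoldPlan",
    "ConfusionCounts",
    "EvalReport",
    "stratified_kfold",
    "confusion",
    "metrics",
    "f1",
    "roc_auc",
    "cross_validate",
]

METRIC_NAMES = ("sensitivity", "specificity", "precision", "f1", "accuracy", "auc")


@dataclass
class FoldPlan:
    """Fold index per row; folds are disjoint, exhaustive and stratified."""

    k: int
    assignments: np.ndarray
    seed: int


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class EvalReport:
    """Per-fold metrics, their mean/SD summary, and the ROC curves."""

    fold_metrics: pd.DataFrame
    summary: pd.DataFrame
    roc_curves: list = field(default_factory=list)
    mean_roc: tuple | None = None
    seed: int | None = None

    def save(self, out_dir, plot: bool = True) -> Path:
        """Write per-fold + summary CSVs and a ROC overlay figure."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.fold_metrics.to_csv(out / "fold_metrics.csv", index_label="fold")
        self.summary.to_csv(out / "summary.csv")
        if plot:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(5, 5))
            for i, (fpr, tpr) in enumerate(self.roc_curves):
                ax.plot(fpr, tpr, alpha=0.4, lw=1, label=f"fold {i}")
            if self.mean_roc is not None:
                ax.plot(*self.mean_roc, "k-", lw=2, label="mean ROC")
            ax.plot([0, 1], [0, 1], "--", color="gray", lw=1)
            ax.set_xlabel("false positive rate")
            ax.set_ylabel("true positive rate")
            ax.legend(fontsize=6)
            fig.savefig(out / "roc.png", dpi=120)
            plt.close(fig)
        return out


def stratified_kfold(labels, k: int = 10, seed: int = 0) -> FoldPlan:
    """Partition rows into k class-balanced folds (deterministic per seed)."""
    y = np.asarray(labels).ravel()
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    _, class_counts = np.unique(y, return_counts=True)
    if class_counts.min() < k:
        raise ValueError(
            f"every class needs >= k members; smallest class has {class_counts.min()} < {k}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(y.size, dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((y.size, 1)), y)):
        assignments[test_idx] = fold
    return FoldPlan(k=k, assignments=assignments, seed=seed)


def confusion(y_true, scores, threshold: float = 0.5) -> ConfusionCounts:
    """Threshold scores (inclusive >=) into hard labels and count outcomes."""
    y = np.asarray(y_true).ravel().astype(int)
    pred = (np.asarray(scores).ravel() >= threshold).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (y == 1))),
        tn=int(np.sum((pred == 0) & (y == 0))),
        fp=int(np.sum((pred == 1) & (y == 0))),
        fn=int(np.sum((pred == 0) & (y == 1))),
    )


def metrics(c: ConfusionCounts) -> dict:
    """Sensitivity, specificity, precision and accuracy from the counts."""
    out = {}
    if c.tp + c.fn == 0:
        raise UndefinedStatisticError("sensitivity undefined: no positive ground truth")
    out["sensitivity"] = c.tp / (c.tp + c.fn)
    if c.tn + c.fp == 0:
        raise UndefinedStatisticError("specificity undefined: no negative ground truth")
    out["specificity"] = c.tn / (c.tn + c.fp)
    if c.tp + c.fp == 0:
        raise UndefinedStatisticError("precision undefined: no positive predictions")
    out["precision"] = c.tp / (c.tp + c.fp)
    out["accuracy"] = (c.tp + c.tn) / c.total
    return out


def f1(precision: float, sensitivity: float) -> float:
    """Harmonic mean of precision and sensitivity; 0 when both are 0."""
    if precision == 0 and sensitivity == 0:
        return 0.0
    return 2.0 * precision * sensitivity / (precision + sensitivity)


def roc_auc(y_true, scores):
    """ROC points (sorted by FPR) and the AUC.

    AUC is the Mann-Whitney statistic: the fraction of
    (positive, negative) pairs where the positive scores higher, ties
    counted half.  Invariant under any strictly increasing rescaling of
    the scores.
    """
    y = np.asarray(y_true).ravel().astype(int)
    s = np.asarray(scores, dtype=float).ravel()
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedStatisticError("AUC undefined for a single-class label vector")
    ranks = rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, _ = _sk_roc_curve(y, s)
    return (fpr, tpr), float(auc)


def _mean_roc(curves, grid_size: int = 101):
    """Vertical averaging: mean TPR over a fixed FPR grid."""
    grid = np.linspace(0.0, 1.0, grid_size)
    tprs = []
    for fpr, tpr in curves:
        interp = np.interp(grid, fpr, tpr)
        interp[0] = 0.0
        tprs.append(interp)
    mean_tpr = np.mean(tprs, axis=0)
    mean_tpr[-1] = 1.0
    return grid, mean_tpr


def cross_validate(model_factory, features, labels, k: int = 10, seed: int = 0,
                   plan: FoldPlan | None = None) -> EvalReport:
    """k rounds of train/evaluate with per-round refitting.

    ``model_factory()`` must return a fresh classifier exposing
    ``fit(X, y)``, ``predict_scores(X)`` and a ``threshold`` attribute
    (any feature scaling happens inside ``fit``, on training rows only).
    Undefined per-fold metrics are recorded as NaN with a warning and
    excluded from the mean/SD (sample SD, ddof=1).
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels).ravel().astype(int)
    if plan is None:
        plan = stratified_kfold(y, k=k, seed=seed)
    rows = []
    curves = []
    for fold in range(plan.k):
        test = plan.assignments == fold
        train = ~test
        model = model_factory()
        model.fit(x[train], y[train])
        scores = model.predict_scores(x[test])
        c = confusion(y[test], scores, threshold=model.threshold)
        row = {}
        try:
            row.update(metrics(c))
            row["f1"] = f1(row["precision"], row["sensitivity"])
        except UndefinedStatisticError as exc:
            warnings.warn(f"fold {fold}: {exc}", stacklevel=2)
        try:
            (fpr, tpr), auc = roc_auc(y[test], scores)
            row["auc"] = auc
            curves.append((fpr, tpr))
        except UndefinedStatisticError as exc:
            warnings.warn(f"fold {fold}: {exc}", stacklevel=2)
        rows.append({name: row.get(name, np.nan) for name in METRIC_NAMES})
    fold_metrics = pd.DataFrame(rows, columns=list(METRIC_NAMES))
    summary = pd.DataFrame(
        {"mean": fold_metrics.mean(skipna=True), "sd": fold_metrics.std(ddof=1, skipna=True)}
    )
    mean_roc = _mean_roc(curves) if curves else None
    return EvalReport(fold_metrics=fold_metrics, summary=summary,
                      roc_curves=curves, mean_roc=mean_roc, seed=seed)
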