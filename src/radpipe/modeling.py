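"""Classifier training and cross-validated evaluation.

Three classifiers are supported with library defaults — linear
discriminant analysis (pooled covariance), k-nearest neighbours
(Euclidean distance; ``k`` is the only user-settable hyperparameter in
the whole modelling stage) and an RBF support vector machine (C = 1).
The positive class for ROC curves, sensitivity and the confusion matrix
is label 1; hard classifications use a 0.5 posterior threshold (or the
sign of the SVM decision value).

Evaluation is (stratified) k-fold cross-validation.  The global ROC is
the vertical average of the per-fold curves: each fold's TPR is
interpolated onto a fixed FPR grid (0, 0.01, ..., 1) and averaged
pointwise; its AUC is the trapezoid of the averaged curve.  Repeated
evaluation reshuffles the cohort ``n_repeats`` times (seed = base seed +
repeat index) and reports each metric as mean +/- a normal-approximation
95% confidence interval over the repeats.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .tables import feature_columns, validate_table

__all__ = [
    "ModelSpec",
    "CVReport",
    "build_classifier",
    "split_train_test",
    "make_folds",
    "cross_validate",
    "average_roc",
    "repeat_evaluation",
    "evaluate_test_set",
    "plot_roc",
]

FPR_GRID = np.linspace(0.0, 1.0, 101)

METRIC_NAMES = ("auc", "accuracy", "sensitivity", "specificity")


@dataclass(frozen=True)
class ModelSpec:
    """Classifier choice: ``kind`` in {lda, knn, svm}; ``knn_k`` for KNN."""

    kind: str = "lda"
    knn_k: int = 5

    def __post_init__(self) -> None:
        if self.kind not in ("lda", "knn", "svm"):
            raise ValueError(f"unknown model kind: {self.kind!r}")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")


def build_classifier(spec: ModelSpec):
    if spec.kind == "lda":
        return LinearDiscriminantAnalysis()
    if spec.kind == "knn":
        return KNeighborsClassifier(n_neighbors=spec.knn_k)
    return SVC(kernel="rbf", C=1.0)


def _decision_values(clf, x: np.ndarray) -> np.ndarray:
    """Continuous score for the positive class (posterior or margin)."""
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(x)[:, 1]
    return clf.decision_function(x)


def _threshold(clf) -> float:
    return 0.5 if hasattr(clf, "predict_proba") else 0.0


@dataclass
class CVReport:
    """Cross-validation outcome: per-fold, per-repeat and summary views."""

    model: dict
    folds: list[dict] = field(default_factory=list)
    mean_roc_fpr: list[float] = field(default_factory=list)
    mean_roc_tpr: list[float] = field(default_factory=list)
    mean_roc_auc: float = float("nan")
    total_confusion: list[list[int]] = field(default_factory=lambda: [[0, 0], [0, 0]])
    mean_metrics: dict = field(default_factory=dict)
    repeats: list[dict] = field(default_factory=list)
    summary: dict = field(default_factory=dict)
    seeds: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "folds": self.folds,
            "mean_roc": {
                "fpr": self.mean_roc_fpr,
                "tpr": self.mean_roc_tpr,
                "auc": self.mean_roc_auc,
            },
            "total_confusion": self.total_confusion,
            "mean_metrics": self.mean_metrics,
            "repeats": self.repeats,
            "summary": self.summary,
            "seeds": self.seeds,
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(
            json.dumps(self.to_dict(), sort_keys=True, indent=2) + "\n"
        )
        return path


def split_train_test(
    table: pd.DataFrame,
    test_fraction: float,
    stratify: bool = True,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint train/test partition; ``test_fraction=0`` keeps all rows
    in training (CV-only mode for small cohorts)."""
    if not 0 <= test_fraction < 1:
        raise ValueError("test_fraction must lie in [0, 1)")
    validate_table(table)
    if test_fraction == 0:
        return table.copy(), table.iloc[0:0].copy()
    rng = np.random.default_rng(seed)
    y = table["label"].to_numpy()
    test_idx: list[int] = []
    if stratify:
        for cls in np.unique(y):
            idx = np.nonzero(y == cls)[0]
            n_test = int(round(test_fraction * idx.size))
            test_idx.extend(rng.permutation(idx)[:n_test].tolist())
    else:
        n_test = int(round(test_fraction * len(table)))
        test_idx = rng.permutation(len(table))[:n_test].tolist()
    test_mask = np.zeros(len(table), dtype=bool)
    test_mask[test_idx] = True
    train = table.loc[~test_mask]
    if len(set(train["label"])) < 2:
        raise ValueError("both classes must remain in the training split")
    return train.copy(), table.loc[test_mask].copy()


def make_folds(
    labels: np.ndarray, k: int, stratified: bool = True, seed: int = 0
) -> list[np.ndarray]:
    """Test-index arrays for k-fold CV (stratified keeps class balance)."""
    labels = np.asarray(labels)
    n = labels.size
    if not 2 <= k <= n:
        raise ValueError(f"k must lie in [2, {n}], got {k}")
    cls = StratifiedKFold if stratified else KFold
    splitter = cls(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros(n), labels)]


def _fold_metrics(y_true: np.ndarray, scores: np.ndarray, threshold: float) -> dict:
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y_true == 1)))
    tn = int(np.sum((pred == 0) & (y_true == 0)))
    fp = int(np.sum((pred == 1) & (y_true == 0)))
    fn = int(np.sum((pred == 0) & (y_true == 1)))
    n_pos = tp + fn
    n_neg = tn + fp
    metrics = {
        "accuracy": (tp + tn) / y_true.size,
        "sensitivity": tp / n_pos if n_pos else float("nan"),
        "specificity": tn / n_neg if n_neg else float("nan"),
        "confusion": [[tn, fp], [fn, tp]],
    }
    if n_pos and n_neg:
        fpr, tpr, _ = roc_curve(y_true, scores, pos_label=1)
        metrics["fpr"] = fpr.tolist()
        metrics["tpr"] = tpr.tolist()
        metrics["auc"] = float(_trapezoid_auc(fpr, tpr))
    else:
        metrics["fpr"] = None
        metrics["tpr"] = None
        metrics["auc"] = float("nan")
    return metrics


def cross_validate(
    table: pd.DataFrame,
    model: ModelSpec,
    folds: list[np.ndarray],
    features: list[str] | None = None,
) -> CVReport:
    """Fit/score the model across the folds and aggregate.

    Each fold is held out once; the model is fitted on the remaining
    folds and scored on the held-out rows with a continuous decision
    value.  The total confusion matrix is the elementwise sum over
    folds, so its entries sum to the cohort size.
    """
    validate_table(table)
    feats = features or feature_columns(table)
    x = table[feats].to_numpy(dtype=np.float64)
    y = table["label"].to_numpy(dtype=int)
    n = len(y)
    all_idx = np.arange(n)
    report = CVReport(model={"kind": model.kind, "knn_k": model.knn_k})
    curves = []
    total = np.zeros((2, 2), dtype=int)
    for fi, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        y_train = y[train_idx]
        if len(set(y_train.tolist())) < 2:
            raise ValueError(
                f"training data for fold {fi} contains a single class"
            )
        if model.kind == "knn" and model.knn_k >= train_idx.size:
            raise ValueError("knn_k must be smaller than the training-fold size")
        clf = build_classifier(model)
        clf.fit(x[train_idx], y_train)
        scores = _decision_values(clf, x[test_idx])
        fm = _fold_metrics(y[test_idx], scores, _threshold(clf))
        fm["fold"] = fi
        fm["n_test"] = int(test_idx.size)
        report.folds.append(fm)
        total += np.asarray(fm["confusion"], dtype=int)
        if fm["fpr"] is not None:
            curves.append((np.asarray(fm["fpr"]), np.asarray(fm["tpr"])))
    report.total_confusion = total.tolist()
    if curves:
        grid, mean_tpr, mean_auc = average_roc(curves)
        report.mean_roc_fpr = grid.tolist()
        report.mean_roc_tpr = mean_tpr.tolist()
        report.mean_roc_auc = mean_auc
    report.mean_metrics = {
        name: float(
            np.nanmean([f[name] for f in report.folds])
        )
        for name in METRIC_NAMES
    }
    return report


def average_roc(
    curves: list[tuple[np.ndarray, np.ndarray]],
) -> tuple[np.ndarray, np.ndarray, float]:
    """Vertical ROC averaging on the fixed FPR grid.

    Returns (fpr_grid, mean_tpr, auc) where the AUC is the trapezoid
    area under the averaged curve.
    """
    if not curves:
        raise ValueError("need at least one ROC curve to average")
    interpolated = []
    for fpr, tpr in curves:
        fpr = np.asarray(fpr, dtype=float)
        tpr = np.asarray(tpr, dtype=float)
        interpolated.append(np.interp(FPR_GRID, fpr, tpr))
    mean_tpr = np.mean(interpolated, axis=0)
    return FPR_GRID.copy(), mean_tpr, float(np.trapezoid(mean_tpr, FPR_GRID))


def repeat_evaluation(
    table: pd.DataFrame,
    model: ModelSpec,
    k: int = 10,
    stratified: bool = True,
    n_repeats: int = 10,
    base_seed: int = 0,
    features: list[str] | None = None,
) -> CVReport:
    """Repeated reshuffled k-fold CV with mean +/- 95% CI summaries.

    Repeat r shuffles the cohort with seed ``base_seed + r`` and re-runs
    the cross-validation.  The summary reports, per metric, the mean
    over repeats and the normal-approximation half-width
    ``1.96 * sd / sqrt(n_repeats)`` (omitted when ``n_repeats == 1``).
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    validate_table(table)
    per_repeat: list[dict] = []
    seeds = []
    last = None
    for r in range(n_repeats):
        seed = base_seed + r
        seeds.append(seed)
        rng = np.random.default_rng(seed)
        shuffled = table.iloc[rng.permutation(len(table))].reset_index(drop=True)
        folds = make_folds(
            shuffled["label"].to_numpy(), k, stratified=stratified, seed=seed
        )
        rep = cross_validate(shuffled, model, folds, features=features)
        entry = {"repeat": r, "seed": seed}
        entry.update(rep.mean_metrics)
        entry["mean_roc_auc"] = rep.mean_roc_auc
        entry["total_confusion"] = rep.total_confusion
        per_repeat.append(entry)
        last = rep

    report = CVReport(model={"kind": model.kind, "knn_k": model.knn_k})
    report.folds = last.folds
    report.mean_roc_fpr = last.mean_roc_fpr
    report.mean_roc_tpr = last.mean_roc_tpr
    report.mean_roc_auc = last.mean_roc_auc
    report.total_confusion = last.total_confusion
    report.mean_metrics = last.mean_metrics
    report.repeats = per_repeat
    report.seeds = seeds
    summary = {}
    for name in METRIC_NAMES:
        values = np.asarray([r[name] for r in per_repeat], dtype=float)
        entry = {"mean": float(np.nanmean(values))}
        if n_repeats > 1:
            half = 1.96 * float(np.nanstd(values, ddof=1)) / np.sqrt(n_repeats)
            entry["ci95"] = [entry["mean"] - half, entry["mean"] + half]
            entry["ci95_halfwidth"] = half
        summary[name] = entry
    report.summary = summary
    return report


def evaluate_test_set(
    fitted_clf, test: pd.DataFrame, features: list[str] | None = None
) -> dict | None:
    """Score a fitted classifier on a held-out table.

    Returns the fold-style metric dict, or None (with no metrics) for an
    empty test set.  A single-class test set has a defined accuracy but
    no AUC.
    """
    if len(test) == 0:
        return None
    feats = features or feature_columns(test)
    x = test[feats].to_numpy(dtype=np.float64)
    y = test["label"].to_numpy(dtype=int)
    scores = _decision_values(fitted_clf, x)
    return _fold_metrics(y, scores, _threshold(fitted_clf))


def plot_roc(report: CVReport, path: str | Path) -> Path:
    """Plot per-fold ROC curves and the vertical average."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(5, 5))
    for fm in report.folds:
        if fm["fpr"] is not None:
            ax.plot(fm["fpr"], fm["tpr"], alpha=0.3, lw=1)
    if report.mean_roc_fpr:
        ax.plot(
            report.mean_roc_fpr,
            report.mean_roc_tpr,
            "k-",
            lw=2,
            label=f"mean ROC (AUC={report.mean_roc_auc:.3f})",
        )
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
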