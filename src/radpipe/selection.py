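"""Feature scoring, selection and the radiomics score.

Three univariate scoring methods rank features against the binary label:

* ``pbc`` — point-biserial correlation, identical to the Pearson
  correlation between the feature and the 0/1 label;
* ``ttest`` — the Welch two-sample t statistic;
* ``relieff`` — ReliefF weights with k nearest hits/misses on
  min-max-scaled features.

The hybrid descriptive-inferential selector walks down the ranking: at
cycle m it fits a logistic regression on the top-m features and compares
the model's likelihood-ratio p-value (against the intercept-only model,
chi-square with m degrees of freedom) with the previous cycle's; the
first non-improving cycle stops the procedure and the last accepted
model is returned (at least one feature is always kept).

The alternative is L1-penalized (LASSO) logistic regression on
z-standardized features: the penalty is chosen on a descending
log-spaced grid by minimum cross-validated binomial deviance, and the
surviving nonzero coefficients define the signature.

Either way the model is summarized by the radiomics score (radscore):
the per-patient linear combination ``b0 + sum_j b_j x_j`` of the
selected features with their fitted coefficients.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .tables import feature_columns, validate_table

__all__ = [
    "ScoreList",
    "SelectionResult",
    "score_features",
    "hybrid_select",
    "lasso_select",
    "compute_radscore",
    "save_selection_report",
    "plot_scores",
]


@dataclass
class ScoreList:
    """Per-feature scores and the induced rank order.

    Ranking sorts by |score| descending; exact ties break
    lexicographically by feature name so the order is deterministic.
    """

    method: str
    scores: pd.Series
    order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.order:
            df = pd.DataFrame(
                {"name": self.scores.index, "abs": self.scores.abs()}
            )
            df = df.sort_values(
                ["abs", "name"], ascending=[False, True], kind="mergesort"
            )
            self.order = df["name"].tolist()


@dataclass
class SelectionResult:
    """Outcome of a selection run: the signature and how it was reached."""

    method: str
    selected: list[str]
    coefficients: dict[str, float]
    intercept: float
    p_trajectory: list[float] = field(default_factory=list)
    include_intercept: bool = True
    lambda_chosen: float | None = None
    lambda_path: list[float] | None = None
    cv_deviance: list[float] | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "selected": self.selected,
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "intercept": float(self.intercept),
            "include_intercept": self.include_intercept,
            "p_trajectory": [float(p) for p in self.p_trajectory],
            "lambda_chosen": self.lambda_chosen,
            "lambda_path": self.lambda_path,
            "cv_deviance": self.cv_deviance,
            "warnings": self.warnings,
        }


def _relieff_weights(
    x: np.ndarray, y: np.ndarray, names: list[str], k: int
) -> np.ndarray:
    """ReliefF for a binary outcome, every sample used once.

    Features are min-max scaled so per-feature differences are
    comparable; neighbour distances are Manhattan on the scaled values.
    Neighbour ties are broken by sample index, which is itself stable
    under fixed row order.
    """
    n, p = x.shape
    span = x.max(axis=0) - x.min(axis=0)
    span[span == 0] = 1.0
    xs = (x - x.min(axis=0)) / span
    weights = np.zeros(p)
    for i in range(n):
        diffs = np.abs(xs - xs[i])
        dist = diffs.sum(axis=1)
        dist[i] = np.inf
        same = np.nonzero(y == y[i])[0]
        same = same[same != i]
        other = np.nonzero(y != y[i])[0]
        k_h = min(k, same.size)
        k_m = min(k, other.size)
        if k_h == 0 or k_m == 0:
            continue
        hits = same[np.argsort(dist[same], kind="stable")[:k_h]]
        misses = other[np.argsort(dist[other], kind="stable")[:k_m]]
        weights -= diffs[hits].mean(axis=0) / n
        weights += diffs[misses].mean(axis=0) / n
    return weights


def score_features(
    table: pd.DataFrame, method: str = "pbc", relieff_k: int = 10
) -> ScoreList:
    """Score every feature against the binary label."""
    validate_table(table)
    y = table["label"].to_numpy(dtype=float)
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes must be present to score features")
    feats = feature_columns(table)
    x = table[feats].to_numpy(dtype=np.float64)

    degenerate = [f for f, s in zip(feats, x.std(axis=0)) if s == 0]
    if degenerate:
        warnings.warn(
            f"zero-variance features scored 0: {degenerate}", stacklevel=2
        )

    if method == "pbc":
        scores = np.zeros(len(feats))
        ys = y - y.mean()
        ynorm = float(np.sqrt(np.sum(ys**2)))
        for j in range(x.shape[1]):
            xc = x[:, j] - x[:, j].mean()
            denom = float(np.sqrt(np.sum(xc**2))) * ynorm
            scores[j] = float(np.sum(xc * ys) / denom) if denom > 0 else 0.0
    elif method == "ttest":
        scores = np.zeros(len(feats))
        g1 = x[y == 1]
        g0 = x[y == 0]
        for j in range(x.shape[1]):
            if x[:, j].std() == 0:
                scores[j] = 0.0
                continue
            scores[j] = float(
                stats.ttest_ind(g1[:, j], g0[:, j], equal_var=False).statistic
            )
    elif method == "relieff":
        scores = _relieff_weights(x, y, feats, k=relieff_k)
        scores[x.std(axis=0) == 0] = 0.0
    else:
        raise ValueError(f"unknown scoring method: {method!r}")

    return ScoreList(method=method, scores=pd.Series(scores, index=feats))


def _logit_lrt(x: np.ndarray, y: np.ndarray) -> tuple[object, float]:
    """Fit logistic regression and return (fit, whole-model LRT p-value)."""
    design = sm.add_constant(x, has_constant="add")
    model = sm.Logit(y, design)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(disp=0, maxiter=200)
    p_mean = y.mean()
    ll_null = len(y) * (
        p_mean * np.log(p_mean) + (1 - p_mean) * np.log(1 - p_mean)
    )
    lrt = 2.0 * (fit.llf - ll_null)
    p_value = float(stats.chi2.sf(max(lrt, 0.0), df=x.shape[1]))
    return fit, p_value


def hybrid_select(table: pd.DataFrame, scores: ScoreList) -> SelectionResult:
    """Hybrid descriptive-inferential selection down the score ranking.

    Cycle m fits a logistic model on the top-m ranked features; the cycle
    is accepted iff its likelihood-ratio p-value is strictly smaller than
    the previous accepted cycle's.  The first non-improving cycle stops
    the walk.  The returned p-value trajectory covers the accepted
    cycles and is strictly decreasing.
    """
    validate_table(table)
    y = table["label"].to_numpy(dtype=float)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 samples per class")
    notes: list[str] = []
    trajectory: list[float] = []
    best = None
    previous_p = np.inf
    for m in range(1, len(scores.order) + 1):
        names = scores.order[:m]
        x = table[names].to_numpy(dtype=np.float64)
        try:
            fit, p_value = _logit_lrt(x, y)
        except Exception as exc:  # complete separation and friends
            if m == 1:
                notes.append(f"cycle 1 separation/convergence issue: {exc}")
                fit = None
                p_value = float(np.finfo(float).tiny)
            else:
                notes.append(f"cycle {m} failed ({exc}); stopping")
                break
        if fit is not None and not fit.mle_retvals.get("converged", True):
            notes.append(f"cycle {m}: logistic fit did not converge")
        if m == 1 or p_value < previous_p:
            trajectory.append(p_value)
            previous_p = p_value
            if fit is not None:
                params = np.asarray(fit.params, dtype=float)
            else:
                params = np.zeros(m + 1)
            best = (names, params)
        else:
            break
    names, params = best
    return SelectionResult(
        method=f"hybrid-{scores.method}",
        selected=list(names),
        coefficients={n: float(b) for n, b in zip(names, params[1:])},
        intercept=float(params[0]),
        p_trajectory=trajectory,
        warnings=notes,
    )


def lasso_select(
    table: pd.DataFrame,
    k_folds: int = 10,
    lambda_grid: np.ndarray | None = None,
    seed: int = 0,
) -> SelectionResult:
    """LASSO logistic selection with minimum-CV-deviance lambda.

    Features are z-standardized first (the L1 penalty is scale
    sensitive); coefficients are reported on the standardized scale.
    The grid descends log-spaced over four decades from ``lambda_max``,
    the smallest penalty that zeroes every coefficient.  Folds are
    stratified so each contains both classes.
    """
    validate_table(table)
    y = table["label"].to_numpy(dtype=float)
    n = len(y)
    if k_folds < 2 or k_folds > n:
        raise ValueError(f"k_folds must be in [2, {n}], got {k_folds}")
    feats = feature_columns(table)
    x = table[feats].to_numpy(dtype=np.float64)
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    xs = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    kept = [f for f, k in zip(feats, keep) if k]

    if lambda_grid is None:
        lambda_max = float(np.abs(xs.T @ (y - y.mean())).max() / n)
        lambda_grid = np.logspace(
            np.log10(lambda_max), np.log10(lambda_max) - 4.0, 100
        )
    lambda_grid = np.asarray(lambda_grid, dtype=float)

    splitter = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    deviance = np.zeros((k_folds, lambda_grid.size))
    eps = 1e-12
    for fi, (train, test) in enumerate(splitter.split(xs, y)):
        for li, lam in enumerate(lambda_grid):
            clf = LogisticRegression(
                l1_ratio=1.0,
                C=1.0 / (lam * len(train)),
                solver="liblinear",
                max_iter=1000,
            )
            clf.fit(xs[train], y[train])
            prob = np.clip(clf.predict_proba(xs[test])[:, 1], eps, 1 - eps)
            deviance[fi, li] = -2.0 * float(
                np.mean(y[test] * np.log(prob) + (1 - y[test]) * np.log(1 - prob))
            )
    mean_dev = deviance.mean(axis=0)
    best_idx = int(np.argmin(mean_dev))
    lam = float(lambda_grid[best_idx])

    final = LogisticRegression(
        l1_ratio=1.0, C=1.0 / (lam * n), solver="liblinear", max_iter=1000
    )
    final.fit(xs, y)
    coefs = final.coef_.ravel()
    selected = [f for f, c in zip(kept, coefs) if c != 0.0]
    return SelectionResult(
        method="lasso",
        selected=selected,
        coefficients={
            f: float(c) for f, c in zip(kept, coefs) if c != 0.0
        },
        intercept=float(final.intercept_[0]),
        lambda_chosen=lam,
        lambda_path=[float(v) for v in lambda_grid],
        cv_deviance=[float(v) for v in mean_dev],
    )


def compute_radscore(
    result: SelectionResult, table: pd.DataFrame, append: bool = False
) -> pd.Series | pd.DataFrame:
    """Per-patient radiomics score for a fitted signature.

    radscore = intercept (if included) + sum_j coef_j * x_j over the
    selected features.  With ``append=True`` the score is added to a
    copy of the table as a ``radscore`` column.
    """
    missing = [f for f in result.selected if f not in table.columns]
    if missing:
        raise KeyError(f"table lacks selected features: {missing}")
    score = np.full(len(table), result.intercept if result.include_intercept else 0.0)
    for name in result.selected:
        score = score + result.coefficients[name] * table[name].to_numpy(float)
    series = pd.Series(score, index=table.index, name="radscore")
    if append:
        out = table.copy()
        out["radscore"] = series
        return out
    return series


def save_selection_report(
    result: SelectionResult, scores: ScoreList, path: str | Path
) -> Path:
    """Write a canonical-JSON selection report (sorted keys)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = result.to_dict()
    payload["ranking"] = {
        "method": scores.method,
        "order": scores.order,
        "scores": {k: float(v) for k, v in scores.scores.items()},
    }
    path.write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")
    return path


def plot_scores(
    scores: ScoreList, result: SelectionResult, path: str | Path
) -> Path:
    """Bar plot of feature scores with the selected features highlighted."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ordered = scores.order
    values = [scores.scores[f] for f in ordered]
    colors = ["crimson" if f in result.selected else "steelblue" for f in ordered]
    fig, ax = plt.subplots(figsize=(max(6, len(ordered) * 0.12), 4))
    ax.bar(range(len(ordered)), values, color=colors)
    ax.set_xlabel("feature rank")
    ax.set_ylabel(f"{scores.method} score")
    ax.set_title("feature scores (selected in red)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
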