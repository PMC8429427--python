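"""Rank graph metrics by their importance for age prediction.

Two rankers are fitted on training data only and their ranks averaged:

* a linear max-margin regressor (linear-kernel support-vector regression)
  on standardized features, with the ridge-style penalty chosen by 5-fold
  cross-validated loss over a log-spaced grid; features are scored by
  normalized absolute coefficient;
* a regression-tree ensemble (bagging or gradient boosting, with the
  method, number of cycles and learning rate chosen by the same seeded
  5-fold search) on unstandardized features, scored by the sum of
  mean-squared-error reductions over all splits on each predictor divided
  by the total number of branch nodes.

The final ordering sorts by average rank (1 = most important); ties break
by the margin-model rank, then by catalog order.  Cross-validation folds
are stratified by age quintile so no fold is age-degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVR

__all__ = [
    "StandardizationStats",
    "FeatureRanking",
    "standardize",
    "rank_by_margin_model",
    "rank_by_tree_ensemble",
    "average_rank",
]

PENALTY_GRID = np.logspace(-4, 2, 13)
ENSEMBLE_CYCLES = (50, 100, 200)
ENSEMBLE_LEARNING_RATES = (0.05, 0.1, 0.3)


@dataclass(frozen=True)
class StandardizationStats:
    """Frozen per-feature training mean and sd, reused for every split."""

    feature_names: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: pd.DataFrame) -> "StandardizationStats":
        mean = X.mean(axis=0).to_numpy()
        sd = X.std(axis=0, ddof=0).to_numpy()
        if np.any(sd == 0):
            bad = [c for c, s in zip(X.columns, sd) if s == 0]
            raise ValueError(f"zero training sd for feature(s) {bad}")
        return cls(tuple(X.columns), mean, sd)

    def checksum(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.mean).tobytes())
        h.update(np.ascontiguousarray(self.sd).tobytes())
        return h.hexdigest()


def standardize(X: pd.DataFrame, stats: StandardizationStats) -> pd.DataFrame:
    """(x - training mean) / training sd, per feature."""
    if tuple(X.columns) != stats.feature_names:
        raise ValueError("feature columns do not match standardization stats")
    return (X - stats.mean) / stats.sd


def _age_quintile_folds(age: np.ndarray, n_splits: int, seed: int):
    """Seeded 5-fold assignment stratified by age quintile."""
    quint = pd.qcut(age, q=5, labels=False, duplicates="drop")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(age)), quint))


def rank_by_margin_model(
    X_std: pd.DataFrame,
    age: np.ndarray,
    seed: int = 0,
    n_splits: int = 5,
) -> tuple[pd.Series, float]:
    """Normalized absolute coefficients of a linear SVR, plus training rmse.

    The penalty grid spans 1e-4..1e2 (13 log-spaced points); the value with
    minimum cross-validated squared loss wins.
    """
    age = np.asarray(age, dtype=float)
    if len(age) < 50:
        raise ValueError("need at least 50 training subjects for ranking")
    folds = _age_quintile_folds(age, n_splits, seed)
    Xa = X_std.to_numpy()

    def _fit(c: float, X: np.ndarray, y: np.ndarray) -> LinearSVR:
        import warnings

        from sklearn.exceptions import ConvergenceWarning

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            return LinearSVR(
                C=c, loss="epsilon_insensitive", epsilon=0.0,
                max_iter=20000, tol=1e-5, random_state=seed,
            ).fit(X, y)

    best_c, best_loss = None, np.inf
    for c in PENALTY_GRID:
        losses = []
        for tr, te in folds:
            mdl = _fit(c, Xa[tr], age[tr])
            losses.append(float(np.mean((mdl.predict(Xa[te]) - age[te]) ** 2)))
        loss = float(np.mean(losses))
        if loss < best_loss:
            best_c, best_loss = c, loss
    model = _fit(best_c, Xa, age)
    coefs = np.abs(model.coef_.ravel())
    peak = coefs.max()
    if peak == 0:
        raise ValueError("all margin-model coefficients are zero")
    rmse = float(np.sqrt(np.mean((model.predict(Xa) - age) ** 2)))
    return pd.Series(coefs / peak, index=X_std.columns, name="margin_weight"), rmse


def _split_importance(tree, n_features: int) -> tuple[np.ndarray, int]:
    """Sum of weighted MSE reductions per feature + branch-node count."""
    t = tree.tree_
    gains = np.zeros(n_features)
    n_branch = 0
    total = t.weighted_n_node_samples[0]
    for node in range(t.node_count):
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:
            continue
        n_branch += 1
        f = t.feature[node]
        gain = (
            t.weighted_n_node_samples[node] * t.impurity[node]
            - t.weighted_n_node_samples[left] * t.impurity[left]
            - t.weighted_n_node_samples[right] * t.impurity[right]
        ) / total
        gains[f] += gain
    return gains, n_branch


def _ensemble_importance(est, n_features: int) -> np.ndarray:
    """MSE-change importance: total split gain / total branch nodes."""
    if hasattr(est, "estimators_"):
        trees = np.asarray(est.estimators_).ravel()
    else:  # pragma: no cover - single tree fallback
        trees = [est]
    gains = np.zeros(n_features)
    branches = 0
    for t in trees:
        g, b = _split_importance(t, n_features)
        gains += g
        branches += b
    if branches == 0:
        return gains
    return gains / branches


def rank_by_tree_ensemble(
    X: pd.DataFrame,
    age: np.ndarray,
    seed: int = 0,
    n_splits: int = 5,
    cycles: tuple[int, ...] = ENSEMBLE_CYCLES,
    learning_rates: tuple[float, ...] = ENSEMBLE_LEARNING_RATES,
) -> tuple[pd.Series, float]:
    """Normalized ensemble importances, plus training rmse.

    Search space: bagged trees x cycles, gradient boosting x cycles x
    learning rate; selection by 5-fold cross-validated squared loss.
    Features are used unstandardized — trees are scale-invariant.
    """
    age = np.asarray(age, dtype=float)
    Xa = X.to_numpy()
    folds = _age_quintile_folds(age, n_splits, seed)

    def _make(method: str, n: int, lr: float | None):
        if method == "bag":
            return RandomForestRegressor(
                n_estimators=n, max_features=1.0, random_state=seed, n_jobs=1
            )
        return GradientBoostingRegressor(
            n_estimators=n, learning_rate=lr, random_state=seed
        )

    candidates: list[tuple[str, int, float | None]] = []
    candidates += [("bag", n, None) for n in cycles]
    candidates += [
        ("boost", n, lr) for n in cycles for lr in learning_rates
    ]

    best_cfg, best_loss = None, np.inf
    for cfg in candidates:
        losses = []
        for tr, te in folds:
            mdl = _make(*cfg).fit(Xa[tr], age[tr])
            losses.append(float(np.mean((mdl.predict(Xa[te]) - age[te]) ** 2)))
        loss = float(np.mean(losses))
        if loss < best_loss:
            best_cfg, best_loss = cfg, loss
    model = _make(*best_cfg).fit(Xa, age)
    imp = _ensemble_importance(model, Xa.shape[1])
    peak = imp.max()
    if peak > 0:
        imp = imp / peak
    rmse = float(np.sqrt(np.mean((model.predict(Xa) - age) ** 2)))
    return pd.Series(imp, index=X.columns, name="ensemble_importance"), rmse


@dataclass
class FeatureRanking:
    """Per-feature scores, ranks and the final average-rank ordering."""

    table: pd.DataFrame  # margin_weight, ensemble_importance, ranks, final order
    ordered_features: list[str]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=True, index_label="metric_name")

    @classmethod
    def from_tsv(cls, path) -> "FeatureRanking":
        table = pd.read_csv(path, sep="\t", index_col="metric_name")
        ordered = list(table.sort_values("final_order").index)
        return cls(table=table, ordered_features=ordered)


def _dense_rank_desc(scores: np.ndarray) -> np.ndarray:
    """Rank 1..n descending by score; ties broken by original position."""
    order = np.lexsort((np.arange(len(scores)), -scores))
    ranks = np.empty(len(scores), dtype=int)
    ranks[order] = np.arange(1, len(scores) + 1)
    return ranks


def average_rank(
    margin_scores: pd.Series, ensemble_scores: pd.Series
) -> FeatureRanking:
    """Average the two rank vectors into the final feature ordering.

    Ranks are 1 = highest score.  The ordering sorts by average rank
    ascending; ties break by margin rank, then by input (catalog) order.
    """
    if list(margin_scores.index) != list(ensemble_scores.index):
        raise ValueError("score vectors must cover the same features")
    m_rank = _dense_rank_desc(margin_scores.to_numpy(dtype=float))
    e_rank = _dense_rank_desc(ensemble_scores.to_numpy(dtype=float))
    avg = (m_rank + e_rank) / 2.0
    order_keys = np.lexsort((np.arange(len(avg)), m_rank, avg))
    final_order = np.empty(len(avg), dtype=int)
    final_order[order_keys] = np.arange(1, len(avg) + 1)
    table = pd.DataFrame(
        {
            "margin_weight": margin_scores.to_numpy(dtype=float),
            "ensemble_importance": ensemble_scores.to_numpy(dtype=float),
            "margin_rank": m_rank,
            "ensemble_rank": e_rank,
            "average_rank": avg,
            "final_order": final_order,
        },
        index=margin_scores.index,
    )
    ordered = list(table.sort_values("final_order").index)
    return FeatureRanking(table=table, ordered_features=ordered)
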