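"""Random-forest regression, three-phase variable selection, permutation null.

The forest is a hand-rolled bagging loop over CART regression trees
(sklearn's ``DecisionTreeRegressor``) because the selection scheme needs
pieces a stock forest does not expose: out-of-bag (OOB) permutation
importance with its per-tree spread, OOB error for arbitrary nested feature
subsets, and (for the interaction module) importance-weighted per-tree
feature subsampling.

Selection follows the published three-phase scheme:

1. *Thresholding* — features are ranked by mean OOB permutation importance
   over k forests; a CART model is fitted to the importance standard
   deviations against rank, and features whose mean importance falls below
   the minimum fitted value are discarded.
2. *Interpretation* — nested forests are grown over prefixes of the ranked
   retained features; the smallest prefix whose mean OOB error is within one
   standard deviation of the minimum is kept.
3. *Prediction* — interpretation variables are added stepwise, kept only
   when they reduce OOB error by more than a data-driven tolerance (the mean
   absolute error jump over the flat tail of the interpretation curve).

The permutation null re-runs selection + forest on B permutations of the
response and reports a one-tailed p-value with the add-one convention,
p = (1 + #{permuted r2 >= observed}) / (B + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from metsynth.exceptions import DegenerateDataError, InvalidConfigError, SchemaError

DEFAULT_N_TREES = 500
DEFAULT_N_THRESHOLD_FORESTS = 25
PAPER_B_PERMUTATIONS = 1000


def _validate_xy(X: pd.DataFrame, y: pd.Series) -> tuple[pd.DataFrame, pd.Series]:
    X = pd.DataFrame(X)
    y = pd.Series(np.asarray(y, dtype=float), index=X.index, name=getattr(y, "name", "y"))
    na_cols = X.columns[X.isna().any()].tolist()
    if na_cols:
        raise SchemaError(f"missing values in feature columns: {na_cols[:10]}")
    if y.isna().any():
        raise SchemaError("missing values in the response")
    if np.ptp(y.to_numpy()) == 0:
        raise DegenerateDataError("constant response")
    if len(X) < 10:
        raise DegenerateDataError("need n >= 10 observations")
    return X, y


@dataclass
class ForestFit:
    """Fitted bagged-CART regression with OOB diagnostics."""

    n_trees: int
    mtry: int
    oob_r2: float                      # percent variance explained, <= 100
    oob_mse: float
    importance: pd.Series              # mean decrease in OOB accuracy (MSE units)
    importance_sd: pd.Series           # spread of the per-tree decreases
    split_importance: pd.Series | None = None  # normalized variance-reduction importance
    seed: int = 0
    feature_names: Sequence[str] = ()
    trees: list = field(repr=False, default_factory=list)
    tree_features: list = field(repr=False, default_factory=list)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Xv = pd.DataFrame(X).loc[:, list(self.feature_names)].to_numpy(dtype=float)
        preds = np.zeros(len(Xv))
        for tree, cols in zip(self.trees, self.tree_features):
            preds += tree.predict(Xv[:, cols])
        return preds / len(self.trees)

    def summary(self) -> str:
        top = self.importance.sort_values(ascending=False).head(10)
        lines = ["Random forest regression (bagged CART)",
                 "=" * 40,
                 f"trees: {self.n_trees}   mtry: {self.mtry}   seed: {self.seed}",
                 f"OOB r2: {self.oob_r2:.2f}%   OOB MSE: {self.oob_mse:.4f}",
                 "", "top importances (mean decrease in OOB accuracy):"]
        for name, value in top.items():
            lines.append(f"  {str(name):<28} {value:.4f}")
        return "\n".join(lines)


class RandomForestRegression:
    """Bagged CART regression trees with OOB error and permutation importance.

    Parameters
    ----------
    n_trees : int
        Forest size (study-fidelity default 500; tests use smaller forests).
    mtry : int, optional
        Split-candidate count per node; default ceil(p / 3) as is standard
        for regression forests.
    feature_weights : array-like, optional
        Per-feature sampling weights; when given, each tree sees a weighted
        subsample of ``subset_size`` features (used by the iterated forest).
    """

    def __init__(self, n_trees: int = DEFAULT_N_TREES, mtry: int | None = None,
                 min_samples_leaf: int = 5, feature_weights=None,
                 subset_size: int | None = None, seed: int = 0):
        if n_trees < 1:
            raise InvalidConfigError("n_trees must be >= 1")
        self.n_trees = n_trees
        self.mtry = mtry
        self.min_samples_leaf = min_samples_leaf
        self.feature_weights = feature_weights
        self.subset_size = subset_size
        self.seed = seed

    def fit(self, X: pd.DataFrame, y: pd.Series,
            compute_importance: bool = True) -> ForestFit:
        X, y = _validate_xy(X, y)
        names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
        yv = y.to_numpy()
        n, p = Xv.shape
        mtry = self.mtry or int(np.ceil(p / 3))
        rng = np.random.default_rng(self.seed)

        weights = None
        if self.feature_weights is not None:
            weights = np.asarray(self.feature_weights, dtype=float)
            weights = np.clip(weights, 0.0, None)
            # floor keeps every feature reachable
            weights = weights / weights.sum() if weights.sum() > 0 else None
        subset_size = self.subset_size or p

        trees, tree_cols = [], []
        oob_sum = np.zeros(n)
        oob_count = np.zeros(n, dtype=int)
        imp_per_tree = np.zeros((self.n_trees, p))
        split_imp = np.zeros(p)

        for b in range(self.n_trees):
            if weights is not None and subset_size < p:
                cols = rng.choice(p, size=subset_size, replace=False, p=weights)
                cols.sort()
            else:
                cols = np.arange(p)
            idx = rng.integers(0, n, n)
            oob = np.ones(n, dtype=bool)
            oob[idx] = False
            tree = DecisionTreeRegressor(
                max_features=min(mtry, len(cols)),
                min_samples_leaf=self.min_samples_leaf,
                random_state=int(rng.integers(0, 2**31 - 1)))
            tree.fit(Xv[np.ix_(idx, cols)], yv[idx])
            trees.append(tree)
            tree_cols.append(cols)
            split_imp[cols] += tree.feature_importances_

            if oob.any():
                X_oob = Xv[np.ix_(oob, cols)]
                pred = tree.predict(X_oob)
                oob_sum[oob] += pred
                oob_count[oob] += 1
                if compute_importance:
                    base_mse = float(np.mean((yv[oob] - pred) ** 2))
                    used = np.unique(tree.tree_.feature[tree.tree_.feature >= 0])
                    for local_f in used:
                        global_f = cols[local_f]
                        Xp = X_oob.copy()
                        Xp[:, local_f] = rng.permutation(Xp[:, local_f])
                        perm_mse = float(np.mean((yv[oob] - tree.predict(Xp)) ** 2))
                        imp_per_tree[b, global_f] = perm_mse - base_mse

        seen = oob_count > 0
        oob_pred = np.full(n, np.nan)
        oob_pred[seen] = oob_sum[seen] / oob_count[seen]
        oob_mse = float(np.mean((yv[seen] - oob_pred[seen]) ** 2))
        var_y = float(np.var(yv[seen], ddof=0))
        oob_r2 = 100.0 * (1.0 - oob_mse / var_y)

        importance = pd.Series(imp_per_tree.mean(axis=0), index=names)
        importance_sd = pd.Series(imp_per_tree.std(axis=0, ddof=1) if self.n_trees > 1
                                  else np.zeros(p), index=names)
        split_importance = pd.Series(
            split_imp / max(1e-12, split_imp.sum()), index=names)
        return ForestFit(n_trees=self.n_trees, mtry=mtry, oob_r2=oob_r2,
                         oob_mse=oob_mse, importance=importance,
                         importance_sd=importance_sd,
                         split_importance=split_importance, seed=self.seed,
                         feature_names=names, trees=trees, tree_features=tree_cols)


def random_forest_regress(X, y, n_trees: int = DEFAULT_N_TREES,
                          mtry: int | None = None, seed: int = 0) -> ForestFit:
    """Functional wrapper over :class:`RandomForestRegression`."""
    return RandomForestRegression(n_trees=n_trees, mtry=mtry, seed=seed).fit(X, y)


@dataclass
class SelectionResult:
    """Nested variable sets from the three selection phases."""

    ranked: list[str]
    importance: pd.Series
    importance_sd: pd.Series
    threshold: float
    threshold_set: list[str]
    interpretation_set: list[str]
    prediction_set: list[str]
    interpretation_errors: list[float]
    seed: int

    def __post_init__(self) -> None:
        if not (set(self.prediction_set) <= set(self.interpretation_set)
                <= set(self.threshold_set) <= set(self.ranked)):
            raise RuntimeError("selection sets violate the nesting invariant")

    def summary(self) -> str:
        lines = ["Three-phase random-forest variable selection",
                 "=" * 44,
                 f"candidates: {len(self.ranked)}",
                 f"threshold set: {len(self.threshold_set)} "
                 f"(importance threshold {self.threshold:.5f})",
                 f"interpretation set ({len(self.interpretation_set)}): "
                 f"{', '.join(map(str, self.interpretation_set[:12]))}"
                 + ("..." if len(self.interpretation_set) > 12 else ""),
                 f"prediction set ({len(self.prediction_set)}): "
                 f"{', '.join(map(str, self.prediction_set))}"]
        return "\n".join(lines)


def vsurf_select(X, y, seed: int = 0,
                 n_threshold_forests: int = DEFAULT_N_THRESHOLD_FORESTS,
                 n_trees: int = DEFAULT_N_TREES,
                 n_interp_runs: int = 10,
                 min_samples_leaf: int = 5) -> SelectionResult:
    """Three-phase (thresholding / interpretation / prediction) selection."""
    X, y = _validate_xy(pd.DataFrame(X), y)
    if X.shape[1] < 2:
        raise InvalidConfigError("need >= 2 candidate features")
    names = list(X.columns)
    root = np.random.SeedSequence(seed)
    seeds = root.generate_state(3 + n_threshold_forests + 2 * len(names) * max(1, n_interp_runs)) % (2**31 - 1)
    seed_iter = iter(int(s) for s in seeds)

    # ---- phase 1: thresholding ------------------------------------------
    imp_runs = []
    for _ in range(n_threshold_forests):
        fit = RandomForestRegression(n_trees=n_trees,
                                     min_samples_leaf=min_samples_leaf,
                                     seed=next(seed_iter)).fit(X, y)
        imp_runs.append(fit.importance)
    imp_matrix = pd.concat(imp_runs, axis=1)
    mean_imp = imp_matrix.mean(axis=1)
    sd_imp = imp_matrix.std(axis=1, ddof=1) if n_threshold_forests > 1 else mean_imp * 0
    order = mean_imp.sort_values(ascending=False).index
    ranked = list(order)

    sd_by_rank = sd_imp.loc[order].to_numpy()
    ranks = np.arange(1, len(ranked) + 1, dtype=float).reshape(-1, 1)
    # regularized CART on the SD-vs-rank curve (rpart-like defaults), so the
    # minimum fitted value reflects the flat noise tail, not a single dip
    cart = DecisionTreeRegressor(min_samples_split=20, min_samples_leaf=7,
                                 ccp_alpha=0.01 * float(np.var(sd_by_rank)),
                                 random_state=0)
    cart.fit(ranks, sd_by_rank)
    threshold = float(cart.predict(ranks).min())
    threshold_set = [f for f in ranked if mean_imp[f] >= threshold]
    if not threshold_set:
        threshold_set = ranked[:1]

    # ---- phase 2: interpretation ----------------------------------------
    errors, error_sds = [], []
    for j in range(1, len(threshold_set) + 1):
        sub = X.loc[:, threshold_set[:j]]
        errs = [RandomForestRegression(n_trees=n_trees,
                                       min_samples_leaf=min_samples_leaf,
                                       seed=next(seed_iter)).fit(
                    sub, y, compute_importance=False).oob_mse
                for _ in range(n_interp_runs)]
        errors.append(float(np.mean(errs)))
        error_sds.append(float(np.std(errs, ddof=1)) if n_interp_runs > 1 else 0.0)
    jmin = int(np.argmin(errors))
    bar = errors[jmin] + error_sds[jmin]
    j_keep = next(j for j, e in enumerate(errors) if e <= bar)
    interpretation_set = threshold_set[: j_keep + 1]

    # ---- phase 3: prediction --------------------------------------------
    tail = np.abs(np.diff(errors[j_keep:])) if j_keep + 1 < len(errors) else np.abs(np.diff(errors))
    tol = float(np.mean(tail)) if len(tail) else 0.0
    prediction_set = [interpretation_set[0]]

    def mean_err(cols: list[str]) -> float:
        return float(np.mean([
            RandomForestRegression(n_trees=n_trees,
                                   min_samples_leaf=min_samples_leaf,
                                   seed=next(seed_iter)).fit(
                X.loc[:, cols], y, compute_importance=False).oob_mse
            for _ in range(max(1, n_interp_runs // 2))]))

    err_prev = mean_err(prediction_set)
    for feature in interpretation_set[1:]:
        err_new = mean_err(prediction_set + [feature])
        if err_prev - err_new > tol:
            prediction_set.append(feature)
            err_prev = err_new

    return SelectionResult(ranked=ranked, importance=mean_imp,
                           importance_sd=sd_imp, threshold=threshold,
                           threshold_set=threshold_set,
                           interpretation_set=interpretation_set,
                           prediction_set=prediction_set,
                           interpretation_errors=errors, seed=seed)


@dataclass
class PermutationNullResult:
    """Observed statistic vs its permutation null distribution."""

    B: int
    observed_r2: float
    permuted_r2: np.ndarray
    p: float

    def __post_init__(self) -> None:
        expected = (1 + int(np.sum(self.permuted_r2 >= self.observed_r2))) / (self.B + 1)
        if not np.isclose(self.p, expected):
            raise RuntimeError("p-value inconsistent with stored permutation vector")

    def summary(self) -> str:
        return (f"Permutation null (B={self.B}): observed r2 = "
                f"{self.observed_r2:.2f}%, null mean = "
                f"{float(np.mean(self.permuted_r2)):.2f}%, one-tailed p = {self.p:.4f}")


def selection_r2_statistic(n_trees: int = DEFAULT_N_TREES,
                           n_threshold_forests: int = DEFAULT_N_THRESHOLD_FORESTS,
                           n_interp_runs: int = 10) -> Callable:
    """Statistic used by the study: select variables, then OOB r2 of a
    standard forest fitted on the interpretation set."""

    def stat(X: pd.DataFrame, y: pd.Series, seed: int) -> float:
        sel = vsurf_select(X, y, seed=seed, n_trees=n_trees,
                           n_threshold_forests=n_threshold_forests,
                           n_interp_runs=n_interp_runs)
        fit = RandomForestRegression(n_trees=n_trees, seed=seed + 1).fit(
            X.loc[:, sel.interpretation_set], y, compute_importance=False)
        return fit.oob_r2

    return stat


def forest_r2_statistic(n_trees: int = 100) -> Callable:
    """Cheaper statistic (no selection): OOB r2 of one forest on all features."""

    def stat(X: pd.DataFrame, y: pd.Series, seed: int) -> float:
        return RandomForestRegression(n_trees=n_trees, seed=seed).fit(
            X, y, compute_importance=False).oob_r2

    return stat


def permutation_null(X, y, B: int = PAPER_B_PERMUTATIONS, seed: int = 0,
                     stat: Callable | None = None) -> PermutationNullResult:
    """One-tailed permutation test of the selection r2 against a permuted
    response. ``stat(X, y, seed) -> r2`` defaults to the full
    selection-then-forest statistic the study used."""
    if B < 19:
        raise InvalidConfigError("B < 19 gives no p-value resolution")
    X, y = _validate_xy(pd.DataFrame(X), y)
    stat = stat or selection_r2_statistic()
    rng = np.random.default_rng(seed)
    observed = stat(X, y, seed=int(rng.integers(0, 2**31 - 1)))
    permuted = np.empty(B)
    for b in range(B):
        y_perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        permuted[b] = stat(X, y_perm, seed=int(rng.integers(0, 2**31 - 1)))
    p = (1 + int(np.sum(permuted >= observed))) / (B + 1)
    return PermutationNullResult(B=B, observed_r2=observed, permuted_r2=permuted, p=p)
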