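"""Count-table preprocessing and co-occurrence module detection.

Covers the microbiome/diet dimension-reduction stages: rarefaction to a
fixed read depth (default 19,986), a strict >20% prevalence filter,
per-1,000-kcal diet normalization, SparCC compositional correlation
(Friedman-Alm log-ratio variance estimator with iterative strong-pair
exclusion), shared-minimum-distance (SMD) module detection on a
complete-linkage dendrogram, and summation summarization of module members.

A module is a maximal dendrogram subtree in which EVERY pairwise correlation
meets the threshold (SparCC minimum R 0.35 for microbiome; Pearson r^2 0.75,
with r > 0, for diet); maximality makes modules pairwise disjoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from metsynth.exceptions import DegenerateDataError, InvalidConfigError, SchemaError
from metsynth.synthetic import CountTable

RAREFACTION_DEPTH = 19_986
PREVALENCE_MIN_FRACTION = 0.2
SPARCC_MIN_R = 0.35
DIET_R2_CUTOFF = 0.75


def _as_df(table) -> pd.DataFrame:
    return table.counts if isinstance(table, CountTable) else table


def rarefy(table, depth: int = RAREFACTION_DEPTH,
           seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples whose total is below ``depth`` are dropped with a warning; a
    sample whose total equals ``depth`` is returned unchanged.
    """
    if depth <= 0:
        raise InvalidConfigError("rarefaction depth must be >= 1")
    df = _as_df(table)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    totals = df.sum(axis=0)
    shallow = totals.index[totals < depth]
    if len(shallow):
        warnings.warn(f"dropping {len(shallow)} sample(s) below depth {depth}: "
                      f"{list(shallow[:5])}...")
    kept = df.drop(columns=shallow)
    out = {}
    for sample in kept.columns:
        col = kept[sample].to_numpy(dtype=np.int64)
        if col.sum() == depth:
            out[sample] = col
        else:
            out[sample] = rng.multivariate_hypergeometric(col, depth)
    return pd.DataFrame(out, index=kept.index)


def prevalence_filter(table, min_fraction: float = PREVALENCE_MIN_FRACTION) -> pd.DataFrame:
    """Keep features present (nonzero) in strictly more than ``min_fraction``
    of samples."""
    if not 0.0 < min_fraction < 1.0:
        raise InvalidConfigError("min_fraction must lie in (0, 1)")
    df = _as_df(table)
    if df.size == 0:
        raise SchemaError("empty count table")
    prevalence = (df > 0).mean(axis=1)
    return df.loc[prevalence > min_fraction]


def normalize_per_kcal(diet: pd.DataFrame, kcal: pd.Series) -> pd.DataFrame:
    """Scale each subject's dietary values to per-1,000-kcal units."""
    kcal = kcal.reindex(diet.index)
    if kcal.isna().any() or (kcal <= 0).any():
        raise DegenerateDataError("kcal must be positive for every subject")
    return diet.mul(1000.0 / kcal, axis=0)


@dataclass
class CorrelationMatrix:
    """Symmetric feature x feature correlation estimates with a method tag."""

    values: pd.DataFrame
    method: str
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if v.shape[0] != v.shape[1] or not np.allclose(v, v.T, atol=1e-10):
            raise SchemaError("correlation matrix must be square and symmetric")
        if np.nanmax(np.abs(v)) > 1 + 1e-9:
            raise SchemaError("correlations must lie in [-1, 1]")


def _basis_variance_system(T: np.ndarray, excluded: set[tuple[int, int]]) -> np.ndarray:
    """Solve for SparCC basis variances given the log-ratio variance matrix.

    Under the sparsity approximation the variances satisfy
    ``(p - 1 - d_i) w_i + sum_{j in partners(i)} w_j = sum_j t_ij`` where
    excluded pairs drop out of both sides.
    """
    p = T.shape[0]
    M = np.ones((p, p))
    np.fill_diagonal(M, float(p - 1))
    b = T.sum(axis=1).astype(float)
    for i, j in excluded:
        M[i, j] = M[j, i] = 0.0
        M[i, i] -= 1.0
        M[j, j] -= 1.0
        b[i] -= T[i, j]
        b[j] -= T[i, j]
    omega2 = np.linalg.solve(M, b)
    return np.clip(omega2, 1e-12, None)


def _sparcc_single(frac: np.ndarray, n_exclusion_rounds: int,
                   exclusion_threshold: float) -> np.ndarray:
    logf = np.log(frac)
    p = logf.shape[0]
    T = np.zeros((p, p))
    for i in range(p):
        diffs = logf[i][None, :] - logf
        T[i] = diffs.var(axis=1, ddof=1)
    excluded: set[tuple[int, int]] = set()
    exclusion_count = np.zeros(p, dtype=int)

    def correlations() -> np.ndarray:
        omega2 = _basis_variance_system(T, excluded)
        omega = np.sqrt(omega2)
        rho = (omega2[:, None] + omega2[None, :] - T) / (2.0 * np.outer(omega, omega))
        np.fill_diagonal(rho, 1.0)
        return np.clip(rho, -1.0, 1.0)

    rho = correlations()
    for _ in range(n_exclusion_rounds):
        masked = np.abs(rho.copy())
        np.fill_diagonal(masked, 0.0)
        for i, j in excluded:
            masked[i, j] = masked[j, i] = 0.0
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        # never strip a feature below 2 remaining partners
        if exclusion_count[i] >= p - 3 or exclusion_count[j] >= p - 3:
            break
        excluded.add((min(i, j), max(i, j)))
        exclusion_count[i] += 1
        exclusion_count[j] += 1
        rho = correlations()
    return rho


def sparcc_correlation(table, n_exclusion_rounds: int = 10,
                       exclusion_threshold: float = 0.8,
                       pseudocount: float = 1.0,
                       n_resamples: int = 1,
                       seed: int = 0) -> CorrelationMatrix:
    """SparCC correlation estimate for a compositional count table.

    Per-pair log-ratio variances t_ij = Var log(x_i/x_j) are converted to
    basis variances via the sparsity-approximation linear system; strongly
    correlated pairs above ``exclusion_threshold`` are iteratively removed
    from the system and it is re-solved. With ``n_resamples > 1`` the
    estimate is averaged over Dirichlet-perturbed count draws (the original
    algorithm's behavior); the default is a single deterministic estimate
    with ``pseudocount`` added.
    """
    df = _as_df(table)
    p, n = df.shape
    if p < 4:
        raise DegenerateDataError("SparCC needs >= 4 features for identifiability")
    counts = df.to_numpy(dtype=float)
    if pseudocount == 0 and (counts.sum(axis=1) == 0).any():
        raise DegenerateDataError("all-zero feature with pseudocount=0")
    rng = np.random.default_rng(seed)
    estimates = []
    for b in range(max(1, n_resamples)):
        if n_resamples > 1:
            frac = np.column_stack(
                [rng.dirichlet(counts[:, j] + pseudocount) for j in range(n)])
        else:
            shifted = counts + pseudocount
            frac = shifted / shifted.sum(axis=0, keepdims=True)
        estimates.append(_sparcc_single(frac, n_exclusion_rounds, exclusion_threshold))
    rho = np.mean(estimates, axis=0)
    values = pd.DataFrame(rho, index=df.index, columns=df.index)
    return CorrelationMatrix(values=values, method="sparcc", meta={
        "n_exclusion_rounds": n_exclusion_rounds,
        "exclusion_threshold": exclusion_threshold,
        "pseudocount": pseudocount, "n_resamples": n_resamples})


def pearson_correlation(features: pd.DataFrame) -> CorrelationMatrix:
    """Plain Pearson correlation across columns (features as columns)."""
    return CorrelationMatrix(values=features.corr(method="pearson"),
                             method="pearson")


@dataclass
class ModuleSet:
    """Disjoint feature modules plus detection metadata."""

    modules: Mapping[str, Sequence[str]]
    method: str
    threshold: float
    r_is_squared: bool = False

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for mid, members in self.modules.items():
            if len(members) < 2:
                raise InvalidConfigError(f"module {mid} has < 2 members")
            overlap = seen.intersection(members)
            if overlap:
                raise InvalidConfigError(f"modules overlap on {sorted(overlap)}")
            seen.update(members)

    def member_of(self) -> dict[str, str]:
        return {f: mid for mid, members in self.modules.items() for f in members}


def smd_modules(corr: CorrelationMatrix, min_r: float,
                r_is_squared: bool = False) -> ModuleSet:
    """Shared-minimum-distance module detection.

    Builds a complete-linkage dendrogram on distance 1 - r and returns the
    maximal subtrees in which every pairwise correlation meets the threshold
    (r >= min_r, or r^2 >= min_r with r > 0 when ``r_is_squared``). The
    highest qualifying ancestor wins, so modules are disjoint; features in
    no qualifying subtree stay singletons and are not modules.
    """
    if not 0.0 < min_r < 1.0:
        raise InvalidConfigError("min_r must lie in (0, 1)")
    R = corr.values.to_numpy()
    ids = list(corr.values.index)
    p = len(ids)
    if p < 2:
        return ModuleSet(modules={}, method=corr.method, threshold=min_r,
                         r_is_squared=r_is_squared)
    dist = 1.0 - R
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="complete")

    if r_is_squared:
        ok = (R > 0) & (R ** 2 >= min_r)
    else:
        ok = R >= min_r
    np.fill_diagonal(ok, True)

    # leaves under each internal node of the dendrogram
    members: list[list[int]] = [[i] for i in range(p)]
    for a, b, _, _ in Z:
        members.append(members[int(a)] + members[int(b)])

    def qualifies(tips: list[int]) -> bool:
        sub = ok[np.ix_(tips, tips)]
        return bool(sub.all())

    modules: dict[str, list[str]] = {}
    stack = [2 * p - 2]  # root node id
    found = []
    while stack:
        node = stack.pop()
        tips = members[node]
        if len(tips) >= 2 and qualifies(tips):
            found.append(tips)
        elif node >= p:
            a, b = int(Z[node - p, 0]), int(Z[node - p, 1])
            stack.extend([a, b])
    # deterministic module numbering by first-leaf order
    for k, tips in enumerate(sorted(found, key=lambda t: min(t))):
        modules[f"module_{k}"] = [ids[i] for i in sorted(tips)]
    return ModuleSet(modules=modules, method=corr.method, threshold=min_r,
                     r_is_squared=r_is_squared)


def summarize_modules(table, modules: ModuleSet) -> pd.DataFrame:
    """Replace member rows by their elementwise sum; per-sample totals are
    conserved exactly and non-members pass through in original order."""
    df = _as_df(table)
    member_map = modules.member_of()
    missing = [f for f in member_map if f not in df.index]
    if missing:
        raise SchemaError(f"module members missing from table: {missing[:5]}")
    rows = {}
    emitted: set[str] = set()
    for feature in df.index:
        mid = member_map.get(feature)
        if mid is None:
            rows[feature] = df.loc[feature]
        elif mid not in emitted:
            rows[mid] = df.loc[list(modules.modules[mid])].sum(axis=0)
            emitted.add(mid)
    return pd.DataFrame(rows).T.set_axis(df.columns, axis=1)


def modules_to_frame(modules: ModuleSet) -> pd.DataFrame:
    """Long-format (module id, member id) table for TSV export."""
    records = [(mid, f) for mid, members in modules.modules.items() for f in members]
    return pd.DataFrame(records, columns=["module", "feature"])
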