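"""Spearman/FDR association networks and classical group tests.

Edges carry Spearman rho (average ranks for ties), the two-sided p from the
t approximation, and Benjamini-Hochberg q-values; an edge exists only where
q < the FDR threshold. Named threshold presets match the study settings:
0.25 for feature-feature networks, 0.1 for selected-feature-vs-outcome
correlations, 0.05 for metabolite-vs-outcome correlations.

Also provides the cohort-table group tests: tie-corrected Kruskal-Wallis and
an exact Fisher r x c test by full enumeration over tables with the observed
margins (with a seeded Monte Carlo fallback above the enumeration cap).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from metsynth.exceptions import (DegenerateDataError, EnumerationLimitError,
                                 InvalidConfigError, SchemaError)

FDR_NETWORK = 0.25
FDR_OUTCOME = 0.10
FDR_METABOLITE = 0.05
FDR_PRESETS = {"network": FDR_NETWORK, "outcome": FDR_OUTCOME,
               "metabolite": FDR_METABOLITE}


@dataclass
class Network:
    """Feature graph with rho/p/q edge attributes at an FDR threshold."""

    graph: nx.Graph
    fdr_threshold: float
    tests: pd.DataFrame  # every tested pair: feature_a, feature_b, rho, p, q

    def neighbors_subnetwork(self, node) -> nx.Graph:
        """The hub node plus exactly its incident edges (ego network)."""
        return nx.ego_graph(self.graph, node, radius=1)

    def edges_frame(self) -> pd.DataFrame:
        return self.tests[self.tests["q"] < self.fdr_threshold].reset_index(drop=True)

    def write_graphml(self, path) -> None:
        g = self.graph.copy()
        for _, data in g.nodes(data=True):  # graphml cannot carry None attrs
            if data.get("layer") is None:
                data.pop("layer", None)
        nx.write_graphml(g, path)


def _drop_constant(features: pd.DataFrame) -> pd.DataFrame:
    constant = [c for c in features.columns if features[c].nunique(dropna=True) <= 1]
    if constant:
        warnings.warn(f"skipping constant feature(s): {constant[:10]}")
    return features.drop(columns=constant)


def spearman_network(features: pd.DataFrame, fdr_threshold: float = FDR_NETWORK,
                     layers: pd.Series | None = None) -> Network:
    """All-pairs Spearman network; one BH family over all tested pairs."""
    features = _drop_constant(pd.DataFrame(features))
    cols = list(features.columns)
    if len(cols) < 2:
        raise SchemaError("need >= 2 non-constant features")
    rho_mat, _ = stats.spearmanr(features.to_numpy())
    if np.ndim(rho_mat) == 0:  # scipy collapses the 2-feature case to a scalar
        rho_mat = np.array([[1.0, float(rho_mat)], [float(rho_mat), 1.0]])
    rows = []
    n = len(features)
    for i, j in itertools.combinations(range(len(cols)), 2):
        rho = float(rho_mat[i, j])
        rows.append((cols[i], cols[j], rho, _spearman_pvalue(rho, n)))
    tests = pd.DataFrame(rows, columns=["feature_a", "feature_b", "rho", "p"])
    tests["q"] = multipletests(tests["p"], method="fdr_bh")[1]

    g = nx.Graph()
    for c in cols:
        g.add_node(c, layer=None if layers is None else layers.get(c))
    for _, r in tests[tests["q"] < fdr_threshold].iterrows():
        g.add_edge(r["feature_a"], r["feature_b"], rho=r["rho"], p=r["p"], q=r["q"])
    return Network(graph=g, fdr_threshold=fdr_threshold, tests=tests)


def _spearman_pvalue(rho: float, n: int) -> float:
    """Two-sided p via the t approximation on n - 2 df."""
    if n < 4:
        raise DegenerateDataError("need >= 4 complete observations")
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def outcome_correlations(features: pd.DataFrame, outcome: pd.Series,
                         fdr_threshold: float = FDR_OUTCOME) -> pd.DataFrame:
    """Per-feature Spearman correlation with one outcome, BH-corrected
    across the supplied feature set (the multiple-testing family)."""
    features = pd.DataFrame(features)
    if len(features) != len(outcome):
        raise SchemaError("features and outcome length mismatch")
    features = _drop_constant(features)
    out = np.asarray(outcome, dtype=float)
    rows = []
    for col in features.columns:
        rho, _ = stats.spearmanr(features[col].to_numpy(), out)
        rows.append((col, float(rho), _spearman_pvalue(float(rho), len(out))))
    table = pd.DataFrame(rows, columns=["feature", "rho", "p"])
    table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    table["significant"] = table["q"] < fdr_threshold
    return table.sort_values("q", ignore_index=True)


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with a chi-squared p on k-1 df."""
    df = pd.DataFrame({"v": np.asarray(values, dtype=float),
                       "g": np.asarray(groups)}).dropna()
    samples = [sub["v"].to_numpy() for _, sub in df.groupby("g")]
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise DegenerateDataError("need >= 2 non-empty groups")
    if df["v"].nunique() == 1:
        warnings.warn("all values tied; Kruskal-Wallis degenerate, p = 1")
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def _log_table_probability(table: np.ndarray) -> float:
    """log hypergeometric probability of an r x c table given its margins."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    return (gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
            - gammaln(n + 1) - gammaln(table + 1).sum())


def _enumerate_tables(rows: np.ndarray, cols: np.ndarray):
    """Yield all non-negative integer tables with the given margins."""
    r, c = len(rows), len(cols)

    def fill(row_idx: int, remaining_cols: np.ndarray, acc: list):
        if row_idx == r - 1:
            yield acc + [remaining_cols.copy()]
            return
        target = rows[row_idx]

        def cells(j: int, left: int, current: list):
            if j == c - 1:
                if left <= remaining_cols[j]:
                    yield current + [left]
                return
            for v in range(min(left, remaining_cols[j]) + 1):
                yield from cells(j + 1, left - v, current + [v])

        for row in cells(0, target, []):
            row = np.array(row)
            yield from fill(row_idx + 1, remaining_cols - row, acc + [row])

    yield from fill(0, cols.astype(int).copy(), [])


def fisher_exact_rxc(table, max_tables: int = 2_000_000,
                     monte_carlo: bool = False, n_draws: int = 100_000,
                     seed: int = 0) -> float:
    """Exact Fisher test for an r x c contingency table.

    Enumerates every table with the observed margins and sums hypergeometric
    probabilities <= the observed table's (with a 1 + 1e-7 relative tolerance
    for float jitter). All-zero rows/columns are dropped first. Beyond
    ``max_tables`` an error suggests the seeded Monte Carlo mode, which
    samples tables from the margin-conditional null instead.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or (t < 0).any():
        raise SchemaError("need a non-negative integer matrix")
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return 1.0
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    log_obs = _log_table_probability(t)
    cutoff = log_obs + np.log1p(1e-7)

    if monte_carlo:
        rng = np.random.default_rng(seed)
        hits = 0
        flat = np.repeat(np.arange(len(cols)), cols)
        for _ in range(n_draws):
            perm = rng.permutation(flat)
            sample = np.zeros_like(t)
            start = 0
            for i, ri in enumerate(rows):
                chunk = perm[start:start + ri]
                start += ri
                sample[i] = np.bincount(chunk, minlength=len(cols))
            if _log_table_probability(sample) <= cutoff:
                hits += 1
        return (hits + 1) / (n_draws + 1)

    # bound: each of the first r-1 rows is a composition of its sum into c parts
    c = len(cols)
    bound = 1.0
    for ri in rows[:-1]:
        bound *= float(math.comb(int(ri) + c - 1, c - 1))
    if bound > max_tables:
        raise EnumerationLimitError(
            f"~{bound:.2e} candidate tables exceeds cap {max_tables}; "
            "use monte_carlo=True")

    log_p_sum = -np.inf
    for candidate in _enumerate_tables(rows, cols):
        lp = _log_table_probability(np.vstack(candidate))
        if lp <= cutoff:
            log_p_sum = np.logaddexp(log_p_sum, lp)
    return float(min(1.0, np.exp(log_p_sum)))
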