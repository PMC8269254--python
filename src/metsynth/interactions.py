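"""Feature-interaction detection by iterated, importance-weighted forests.

Iteration 1 is a standard bagged-CART forest; later iterations bias the
per-tree feature pool toward the previous iteration's importances (with a
floor of 1/(10p) so no feature is permanently excluded). From the final
forest, a feature pair is *proximate* in a tree when the two features sit in
adjacent (parent-child) internal nodes anywhere in the tree; the pair's
prevalence is the fraction of trees in which it is proximate at least once,
and an edge is emitted at prevalence >= the threshold (default 0.30).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from metsynth.exceptions import InvalidConfigError
from metsynth.selection import RandomForestRegression, _validate_xy

INTERACTION_PREVALENCE = 0.30
DEFAULT_N_ITERATIONS = 3


def tree_adjacent_pairs(tree, feature_names) -> set[tuple]:
    """Unordered feature pairs occupying parent-child internal nodes."""
    t = tree.tree_
    pairs: set[tuple] = set()
    for parent in range(t.node_count):
        f_parent = t.feature[parent]
        if f_parent < 0:
            continue
        for child in (t.children_left[parent], t.children_right[parent]):
            f_child = t.feature[child]
            if f_child >= 0 and f_child != f_parent:
                a, b = feature_names[f_parent], feature_names[f_child]
                pairs.add((a, b) if str(a) <= str(b) else (b, a))
    return pairs


@dataclass
class InteractionGraph:
    """Undirected feature graph weighted by per-tree adjacency prevalence."""

    graph: nx.Graph
    threshold: float
    prevalence: Mapping[tuple, float] = field(default_factory=dict)
    #: per iteration, fraction of trees whose splits use each feature
    iteration_usage: list = field(default_factory=list)

    def edges_frame(self) -> pd.DataFrame:
        rows = [(a, b, d["prevalence"]) for a, b, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["feature_a", "feature_b", "prevalence"]
                            ).sort_values("prevalence", ascending=False,
                                          ignore_index=True)

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def iterative_forest_interactions(X, y, n_iterations: int = DEFAULT_N_ITERATIONS,
                                  n_trees: int = 300,
                                  min_prevalence: float = INTERACTION_PREVALENCE,
                                  seed: int = 0) -> InteractionGraph:
    """Iterated forest; edges where a pair is tree-adjacent in >= the given
    fraction of the final iteration's trees."""
    if n_iterations < 1:
        raise InvalidConfigError("n_iterations must be >= 1")
    X, y = _validate_xy(pd.DataFrame(X), y)
    names = list(X.columns)
    p = len(names)
    seeds = np.random.SeedSequence(seed).generate_state(n_iterations) % (2**31 - 1)

    weights = None
    fit = None
    usage_per_iteration = []
    for it in range(n_iterations):
        model = RandomForestRegression(
            n_trees=n_trees, seed=int(seeds[it]),
            feature_weights=weights,
            subset_size=None if weights is None else max(5, int(np.ceil(p / 2))))
        fit = model.fit(X, y, compute_importance=False)
        usage = np.zeros(p)
        for tree, cols in zip(fit.trees, fit.tree_features):
            used = np.unique(tree.tree_.feature[tree.tree_.feature >= 0])
            usage[cols[used]] += 1.0
        usage_per_iteration.append(pd.Series(usage / len(fit.trees), index=names))
        # variance-reduction importance drives the reweighting: on noise it
        # stays near-uniform (every tree must split on something), so weights
        # only concentrate when features genuinely reduce impurity
        imp = np.clip(fit.split_importance.to_numpy(), 0.0, None)
        imp = imp / imp.sum() if imp.sum() > 0 else np.full(p, 1.0 / p)
        # half-mixing with the uniform law keeps chance concentrations on
        # uninformative features from snowballing across iterations, while a
        # floor of 1/(10p) guarantees no feature is permanently excluded
        weights = 0.5 * imp + 0.5 / p
        weights = np.clip(weights, 1.0 / (10.0 * p), None)
        weights = weights / weights.sum()

    counts: dict[tuple, int] = {}
    for tree, cols in zip(fit.trees, fit.tree_features):
        local_names = [names[c] for c in cols]
        for pair in tree_adjacent_pairs(tree, local_names):
            counts[pair] = counts.get(pair, 0) + 1
    prevalence = {pair: c / len(fit.trees) for pair, c in counts.items()}

    g = nx.Graph()
    g.add_nodes_from(names)
    for (a, b), prev in prevalence.items():
        if prev >= min_prevalence:
            g.add_edge(a, b, prevalence=prev)
    return InteractionGraph(graph=g, threshold=min_prevalence,
                            prevalence=prevalence,
                            iteration_usage=usage_per_iteration)
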