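"""Spearman/FDR networks, Kruskal-Wallis, exact Fisher r x c."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metsynth import networks as net
from metsynth.exceptions import EnumerationLimitError, SchemaError


def brute_force_bh(pvals):
    """Independent BH: sort, scale by m/i, cummin from the largest."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def test_monotone_pair_is_an_edge(rng):
    x = np.sort(rng.standard_normal(20))
    df = pd.DataFrame({"a": x, "b": np.exp(x), "noise": rng.standard_normal(20)})
    network = net.spearman_network(df, fdr_threshold=0.25)
    assert network.graph.has_edge("a", "b")
    assert network.graph["a"]["b"]["rho"] == 1.0


def test_q_values_match_brute_force_bh(rng):
    df = pd.DataFrame(rng.standard_normal((30, 10)),
                      columns=[f"f{i}" for i in range(10)])
    df["f1"] += 0.8 * df["f0"]
    network = net.spearman_network(df)
    q = network.tests["q"].to_numpy()
    expected = brute_force_bh(network.tests["p"].to_numpy())
    np.testing.assert_allclose(q, expected, rtol=1e-12, atol=0)
    # BH sanity: q >= p elementwise, q non-decreasing in p
    assert (q >= network.tests["p"].to_numpy() - 1e-15).all()
    ordered = network.tests.sort_values("p")["q"].to_numpy()
    assert (np.diff(ordered) >= -1e-15).all()


def test_hub_subnetwork_returns_incident_edges(rng):
    hub = rng.standard_normal(40)
    df = pd.DataFrame({"hub": hub,
                       "a": hub + 0.3 * rng.standard_normal(40),
                       "b": hub + 0.3 * rng.standard_normal(40),
                       "c": rng.standard_normal(40)})
    network = net.spearman_network(df, fdr_threshold=0.25)
    ego = network.neighbors_subnetwork("hub")
    assert set(ego.nodes) == {"hub"} | set(network.graph.neighbors("hub"))


def test_constant_feature_skipped_with_warning(rng):
    df = pd.DataFrame({"a": rng.standard_normal(20), "b": rng.standard_normal(20),
                       "const": np.ones(20)})
    with pytest.warns(UserWarning, match="constant"):
        network = net.spearman_network(df)
    assert "const" not in network.graph.nodes


def test_spearman_invariant_to_monotone_transforms(rng):
    x = rng.standard_normal(30)
    y = x + rng.standard_normal(30)
    r1, _ = stats.spearmanr(x, y)
    df1 = net.outcome_correlations(pd.DataFrame({"f": np.exp(x)}), pd.Series(y))
    assert np.isclose(df1.loc[0, "rho"], r1, atol=1e-12)


def test_outcome_correlations_identity_and_presets(rng):
    y = rng.standard_normal(44)
    feats = pd.DataFrame({"self": y,
                          **{f"n{i}": rng.standard_normal(44) for i in range(5)}})
    table = net.outcome_correlations(feats, pd.Series(y), net.FDR_OUTCOME)
    self_row = table.set_index("feature").loc["self"]
    assert self_row["rho"] == 1.0
    assert self_row["q"] == table["q"].min()
    assert net.FDR_PRESETS == {"network": 0.25, "outcome": 0.1, "metabolite": 0.05}


def test_outcome_correlations_recover_planted(rng):
    """10 of 200 features correlated with the outcome at rho ~ 0.5, n = 44."""
    recovered = []
    for s in range(5):
        g = np.random.default_rng(600 + s)
        z = g.standard_normal(44)
        planted = {f"m{i}" for i in range(10)}
        feats = {}
        for i in range(200):
            name = f"m{i}"
            eff = 0.5 if name in planted else 0.0
            feats[name] = eff * z + np.sqrt(1 - eff ** 2) * g.standard_normal(44)
        table = net.outcome_correlations(pd.DataFrame(feats), pd.Series(z),
                                         net.FDR_METABOLITE)
        hits = set(table.loc[table["significant"], "feature"]) & planted
        recovered.append(len(hits))
    assert np.median(recovered) >= 7


def test_kruskal_wallis_matches_hand_computation():
    values = [1, 2, 3, 10, 11, 12, 20, 21, 22]
    groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
    h, p = net.kruskal_wallis(values, groups)
    # hand computation: ranks 1..9, rank sums 6, 15, 24... wait 6,15,24
    n = 9
    rank_sums = [6, 15, 24]
    expected_h = 12 / (n * (n + 1)) * sum(r ** 2 / 3 for r in rank_sums) - 3 * (n + 1)
    assert abs(h - expected_h) < 1e-10
    assert abs(p - stats.chi2.sf(expected_h, 2)) < 1e-12


def test_kruskal_wallis_edge_cases():
    with pytest.warns(UserWarning, match="tied"):
        _, p = net.kruskal_wallis([5, 5, 5, 5], ["a", "a", "b", "b"])
    assert p == 1.0
    _, p2 = net.kruskal_wallis(list(range(10)) + list(range(100, 110))
                               + list(range(1000, 1010)),
                               ["a"] * 10 + ["b"] * 10 + ["c"] * 10)
    assert p2 < 0.001


def test_fisher_2x2_matches_hypergeometric_oracle():
    table = [[1, 9], [11, 3]]
    mine = net.fisher_exact_rxc(table)
    _, expected = stats.fisher_exact(table)
    assert abs(mine - expected) < 1e-12


def test_fisher_drops_empty_categories():
    assert net.fisher_exact_rxc([[0, 0], [3, 4], [5, 2]]) == \
        net.fisher_exact_rxc([[3, 4], [5, 2]])


def test_fisher_enumeration_probabilities_sum_to_one():
    t = np.array([[3, 2, 4], [1, 5, 2]])
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    total = 0.0
    for cand in net._enumerate_tables(rows, cols):
        total += np.exp(net._log_table_probability(np.vstack(cand)))
    assert abs(total - 1.0) < 1e-9


def test_fisher_monte_carlo_agrees_with_exact():
    table = [[2, 8], [9, 3]]
    exact = net.fisher_exact_rxc(table)
    mc = net.fisher_exact_rxc(table, monte_carlo=True, n_draws=20_000, seed=0)
    assert abs(mc - exact) < 0.02


def test_fisher_enumeration_cap():
    big = np.full((4, 4), 50)
    with pytest.raises(EnumerationLimitError, match="monte_carlo"):
        net.fisher_exact_rxc(big, max_tables=1000)


def test_network_rejects_length_mismatch(rng):
    with pytest.raises(SchemaError):
        net.outcome_correlations(pd.DataFrame({"a": np.arange(10.0)}),
                                 pd.Series(np.arange(9.0)))
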