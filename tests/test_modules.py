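"""Rarefaction, filters, SparCC and shared-minimum-distance modules."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metsynth import modules as mod
from metsynth.exceptions import DegenerateDataError, InvalidConfigError, SchemaError


# ---------------------------------------------------------------- rarefaction

def test_rarefy_exact_depth_sample_unchanged():
    df = pd.DataFrame({"s1": [60, 30, 10], "s2": [500, 300, 200]},
                      index=["a", "b", "c"])
    out = mod.rarefy(df, depth=100, seed=0)
    assert (out["s1"] == df["s1"]).all()
    assert out["s2"].sum() == 100
    assert (out.le(df)).all().all()


def test_rarefy_drops_shallow_samples():
    df = pd.DataFrame({"deep": [80, 40], "shallow": [5, 5]})
    with pytest.warns(UserWarning, match="dropping 1 sample"):
        out = mod.rarefy(df, depth=100, seed=0)
    assert list(out.columns) == ["deep"]


def test_rarefy_matches_hypergeometric_mean():
    """Mean rarefied count of a feature equals the hypergeometric mean."""
    col = pd.DataFrame({"s": [100, 50, 50]})
    rng = np.random.default_rng(0)
    draws = np.array([mod.rarefy(col, depth=100, seed=rng)["s"].iloc[0]
                      for _ in range(2000)])
    expected = 100 * 100 / 200  # n * K / N
    var = 100 * 0.5 * 0.5 * (200 - 100) / (200 - 1)
    assert abs(draws.mean() - expected) <= 3 * np.sqrt(var / 2000)


def test_rarefy_invalid_depth():
    with pytest.raises(InvalidConfigError):
        mod.rarefy(pd.DataFrame({"s": [5]}), depth=0)


# ---------------------------------------------------------- prevalence filter

def test_prevalence_boundary_is_strict():
    # present in exactly 20% of 10 samples -> removed; 30% -> kept
    df = pd.DataFrame([[1, 1] + [0] * 8, [1, 1, 1] + [0] * 7],
                      index=["borderline", "kept"])
    out = mod.prevalence_filter(df, 0.2)
    assert list(out.index) == ["kept"]


def test_prevalence_filter_matches_brute_force(rng):
    df = pd.DataFrame((rng.random((100, 25)) < 0.25).astype(int) *
                      rng.integers(1, 9, (100, 25)))
    out = mod.prevalence_filter(df, 0.2)
    expected = [i for i in df.index if (df.loc[i] > 0).sum() > 0.2 * 25]
    assert list(out.index) == expected


def test_prevalence_filter_empty_table():
    with pytest.raises(SchemaError):
        mod.prevalence_filter(pd.DataFrame())


# ------------------------------------------------------------------- per-kcal

def test_normalize_per_kcal():
    diet = pd.DataFrame({"fiber": [25.0, 10.0]}, index=["a", "b"])
    kcal = pd.Series([2000.0, 1000.0], index=["a", "b"])
    out = mod.normalize_per_kcal(diet, kcal)
    assert out.loc["a", "fiber"] == 12.5
    assert out.loc["b", "fiber"] == 10.0  # 1,000 kcal is the identity
    with pytest.raises(DegenerateDataError):
        mod.normalize_per_kcal(diet, pd.Series([2000.0, 0.0], index=["a", "b"]))


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20, deadline=None)
def test_normalize_per_kcal_elementwise(seed):
    rng = np.random.default_rng(seed)
    diet = pd.DataFrame(rng.uniform(0.1, 50, (5, 3)))
    kcal = pd.Series(rng.uniform(1200, 3500, 5))
    out = mod.normalize_per_kcal(diet, kcal)
    for i in range(5):
        for j in range(3):
            assert np.isclose(out.iat[i, j], diet.iat[i, j] * 1000 / kcal.iloc[i])


# --------------------------------------------------------------------- SparCC

def test_sparcc_proportional_features_near_one(rng):
    base = rng.lognormal(3, 1, (6, 50))
    base[1] = 3.0 * base[0]  # exact proportionality
    counts = pd.DataFrame(np.rint(base).astype(int))
    corr = mod.sparcc_correlation(counts)
    assert corr.values.iloc[0, 1] >= 0.95


def test_sparcc_basis_variances_match_dense_oracle(rng):
    counts = pd.DataFrame(rng.integers(1, 500, (5, 50)))
    frac = (counts.to_numpy() + 1.0)
    frac = frac / frac.sum(axis=0, keepdims=True)
    logf = np.log(frac)
    p = 5
    # independent loop-built variation matrix and linear system
    T = np.zeros((p, p))
    for i, j in itertools.product(range(p), range(p)):
        T[i, j] = np.var(logf[i] - logf[j], ddof=1)
    M = np.ones((p, p)) + np.diag([p - 2.0] * p)
    omega2 = np.linalg.solve(M, T.sum(axis=1))
    mine = mod._basis_variance_system(T, excluded=set())
    np.testing.assert_allclose(mine, omega2, atol=1e-6)


def test_sparcc_null_is_centered(rng):
    clean = 0
    for s in range(20):
        g = np.random.default_rng(500 + s)
        logabund = g.standard_normal((20, 200)) + g.normal(0, 1, 20)[:, None]
        props = np.exp(logabund)
        props /= props.sum(axis=0, keepdims=True)
        counts = np.column_stack([g.multinomial(20_000, props[:, j])
                                  for j in range(200)])
        corr = mod.sparcc_correlation(pd.DataFrame(counts)).values.to_numpy()
        off = corr[~np.eye(20, dtype=bool)]
        clean += np.abs(off).max() <= 0.3
    assert clean >= 19  # >= 95% of seeds


def test_sparcc_requires_four_features():
    with pytest.raises(DegenerateDataError):
        mod.sparcc_correlation(pd.DataFrame(np.ones((3, 10), dtype=int)))


# --------------------------------------------------------------- SMD modules

def _corr_from_blocks(p, blocks, r):
    m = np.eye(p)
    for block in blocks:
        for i, j in itertools.permutations(block, 2):
            m[i, j] = r
    return mod.CorrelationMatrix(values=pd.DataFrame(
        m, index=[f"f{i}" for i in range(p)], columns=[f"f{i}" for i in range(p)]),
        method="test")


def test_identity_correlation_gives_no_modules():
    corr = _corr_from_blocks(5, [], 0.0)
    assert mod.smd_modules(corr, min_r=0.35).modules == {}


def test_planted_block_is_one_module():
    corr = _corr_from_blocks(6, [(0, 1, 2)], 0.9)
    ms = mod.smd_modules(corr, min_r=0.35)
    assert list(ms.modules.values()) == [["f0", "f1", "f2"]]


def exhaustive_smd_oracle(R: np.ndarray, min_r: float) -> list[set[int]]:
    """All maximal leaf sets that (a) are dendrogram subtrees and (b) have
    every pairwise r >= min_r — by exhaustive enumeration of subtrees."""
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform
    p = R.shape[0]
    d = 1.0 - R
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method="complete")
    members = [[i] for i in range(p)]
    for a, b, _, _ in Z:
        members.append(members[int(a)] + members[int(b)])
    qualifying = []
    for tips in members:
        if len(tips) < 2:
            continue
        if all(R[i, j] >= min_r for i, j in itertools.combinations(tips, 2)):
            qualifying.append(set(tips))
    return [q for q in qualifying
            if not any(q < other for other in qualifying)]


def test_smd_matches_exhaustive_subtree_oracle(rng):
    for _ in range(25):
        p = int(rng.integers(4, 9))
        A = rng.uniform(-1, 1, (p, p))
        R = np.clip((A + A.T) / 2, -0.99, 0.99)
        np.fill_diagonal(R, 1.0)
        ids = [f"f{i}" for i in range(p)]
        corr = mod.CorrelationMatrix(values=pd.DataFrame(R, index=ids, columns=ids),
                                     method="test")
        ms = mod.smd_modules(corr, min_r=0.35)
        mine = sorted(sorted(int(f[1:]) for f in mem) for mem in ms.modules.values())
        oracle = sorted(sorted(s) for s in exhaustive_smd_oracle(R, 0.35))
        assert mine == oracle


def test_smd_r_squared_mode_requires_positive_r():
    # r = -0.9 has r^2 = 0.81 >= 0.75 but must NOT form a module
    corr = _corr_from_blocks(4, [(0, 1)], -0.9)
    assert mod.smd_modules(corr, min_r=0.75, r_is_squared=True).modules == {}
    corr2 = _corr_from_blocks(4, [(0, 1)], 0.9)
    assert len(mod.smd_modules(corr2, min_r=0.75, r_is_squared=True).modules) == 1


def test_module_internal_minimum_meets_threshold(count_table):
    filtered = mod.prevalence_filter(count_table.counts, 0.2)
    corr = mod.sparcc_correlation(filtered, seed=0)
    ms = mod.smd_modules(corr, min_r=0.35)
    assert ms.modules  # the generator plants one module
    for members in ms.modules.values():
        sub = corr.values.loc[members, members].to_numpy()
        assert sub[~np.eye(len(members), dtype=bool)].min() >= 0.35


# -------------------------------------------------------------- summarization

def test_summarize_conserves_totals_and_sums_members(count_table):
    df = count_table.counts
    ms = mod.ModuleSet(modules={"m0": ["OTU_0000", "OTU_0001", "OTU_0002"]},
                       method="test", threshold=0.35)
    out = mod.summarize_modules(df, ms)
    np.testing.assert_array_equal(out.sum(axis=0).to_numpy(),
                                  df.sum(axis=0).to_numpy())
    np.testing.assert_array_equal(
        out.loc["m0"].to_numpy(),
        df.loc[["OTU_0000", "OTU_0001", "OTU_0002"]].sum(axis=0).to_numpy())
    # feature count shrinks by sum(size - 1)
    assert out.shape[0] == df.shape[0] - 2


def test_summarize_missing_member_errors(count_table):
    ms = mod.ModuleSet(modules={"m0": ["OTU_0000", "NOPE"]},
                       method="test", threshold=0.35)
    with pytest.raises(SchemaError):
        mod.summarize_modules(count_table.counts, ms)


def test_moduleset_rejects_overlap_and_singletons():
    with pytest.raises(InvalidConfigError):
        mod.ModuleSet(modules={"a": ["x", "y"], "b": ["y", "z"]},
                      method="t", threshold=0.5)
    with pytest.raises(InvalidConfigError):
        mod.ModuleSet(modules={"a": ["x"]}, method="t", threshold=0.5)
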