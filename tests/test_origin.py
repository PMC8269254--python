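"""Metabolite origin attribution and rank-based regression."""

import itertools

import numpy as np
import pandas as pd
import pytest

from metsynth import origin as org
from metsynth import synthetic as syn
from metsynth.exceptions import DegenerateDataError, SchemaError
from metsynth.synthetic import MouseMetabolome, ReactionMap


@pytest.fixture()
def toy_map() -> tuple[ReactionMap, list[str]]:
    rmap = ReactionMap(
        gene_reactions={"g1": ["r1"], "g2": ["r2"], "g3": ["r1", "r3"],
                        "g4": ["r4"]},
        reactions={"r1": {"substrates": ["S"], "products": ["C1", "C2"]},
                   "r2": {"substrates": ["S"], "products": ["C3"]},
                   "r3": {"substrates": ["C1"], "products": ["C4"]},
                   "r4": {"substrates": ["S"], "products": ["C2", "C5"]}})
    return rmap, ["g1", "g2", "g3", "g4"]


def test_producible_single_gene(toy_map):
    rmap, _ = toy_map
    assert org.producible_compounds(["g1"], rmap) == {"C1", "C2"}
    assert org.producible_compounds([], rmap) == set()


def test_producible_monotone_over_all_subsets(toy_map):
    rmap, genes = toy_map
    for r in range(len(genes) + 1):
        for subset in itertools.combinations(genes, r):
            prods = org.producible_compounds(subset, rmap)
            for bigger in itertools.combinations(genes, min(r + 1, len(genes))):
                if set(subset) <= set(bigger):
                    assert prods <= org.producible_compounds(bigger, rmap)


def test_producible_unknown_genes_warn(toy_map):
    rmap, _ = toy_map
    with pytest.warns(UserWarning, match="unknown gene"):
        out = org.producible_compounds(["g1", "mystery"], rmap)
    assert out == {"C1", "C2"}


def _mouse(seed, n_compounds=20, lfc=None, n_per_arm=8):
    rng = np.random.default_rng(seed)
    cids = [f"C{i}" for i in range(n_compounds)]
    base = rng.normal(10, 1, n_compounds)
    log_i = base[:, None] + 0.5 * rng.standard_normal((n_compounds, 2 * n_per_arm))
    if lfc:
        for cid, fc in lfc.items():
            log_i[cids.index(cid), n_per_arm:] += fc * np.log(2)
    samples = [f"g{i}" for i in range(n_per_arm)] + [f"h{i}" for i in range(n_per_arm)]
    return MouseMetabolome(
        intensities=pd.DataFrame(np.exp(log_i), index=cids, columns=samples),
        design=pd.Series(["germfree"] * n_per_arm + ["colonized"] * n_per_arm,
                         index=samples))


def test_mouse_differential_null_type_i_control():
    any_hit = 0
    for s in range(20):
        sig, _ = org.mouse_differential(_mouse(s))
        any_hit += bool(sig)
    assert any_hit <= 2  # <= 10% of seeds with any false finding


def test_mouse_differential_recovers_planted_shifts():
    recovered = []
    for s in range(20):
        lfc = {f"C{i}": 2.0 for i in range(10)}
        sig, table = org.mouse_differential(_mouse(100 + s, n_compounds=60, lfc=lfc))
        recovered.append(len(sig & set(lfc)))
        assert (table["q"] >= table["p"] - 1e-15).all()
    assert np.median(recovered) >= 8


def test_mouse_differential_requires_replication():
    from metsynth.exceptions import InvalidConfigError
    m = _mouse(0)
    # a single germfree animal violates the >= 2 per-arm invariant up front
    with pytest.raises(InvalidConfigError):
        MouseMetabolome(intensities=m.intensities.iloc[:, [0, 8, 9, 10]],
                        design=m.design.iloc[[0, 8, 9, 10]])


def test_combine_origin_invariant_random_fixtures(rng):
    compounds = [f"C{i}" for i in range(100)]
    for _ in range(5):
        prod = set(rng.choice(compounds, 30, replace=False))
        diff = set(rng.choice(compounds, 25, replace=False))
        human = set(rng.choice(compounds, 60, replace=False))
        table = org.combine_origin(prod, diff, human)
        for cid, row in table.iterrows():
            expected = (cid in prod or cid in diff) and cid in human
            assert row["microbiome_associated"] == expected
            if cid in prod and cid in diff:
                assert row["provenance"] == "producible+mouse"
            if cid not in prod and cid not in diff:
                assert not row["microbiome_associated"]


# ------------------------------------------------------------ rank regression

def test_exact_fit_slope_and_zero_dispersion(rng):
    x = rng.standard_normal(30)
    res = org.rank_regression(2.0 * x, pd.DataFrame({"x": x}))
    assert abs(res.params["x"] - 2.0) < 1e-8
    assert res.dispersion < 1e-10


def test_slope_matches_dispersion_grid_oracle():
    rng = np.random.default_rng(4)
    x = rng.standard_normal(8)
    y = 1.5 * x + 0.5 * rng.standard_normal(8)
    res = org.rank_regression(y, pd.DataFrame({"x": x}))
    grid = np.arange(-3.0, 4.0, 0.0005)
    disp = [org._wilcoxon_dispersion(y - b * x) for b in grid]
    best = grid[int(np.argmin(disp))]
    assert abs(res.params["x"] - best) < 1e-3
    # dispersion at the optimum cannot exceed dispersion at beta = 0
    assert res.dispersion <= org._wilcoxon_dispersion(y) + 1e-12


def test_rank_slope_matches_ols_on_gaussian_data():
    rng = np.random.default_rng(9)
    x = rng.standard_normal(120)
    y = 0.8 * x + rng.standard_normal(120)
    res = org.rank_regression(y, pd.DataFrame({"x": x}))
    ols_slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
    ols_se = np.sqrt(np.var(y - ols_slope * x, ddof=2) / np.sum((x - x.mean()) ** 2))
    assert abs(res.params["x"] - ols_slope) < 2 * ols_se


def test_rank_regression_scale_equivariance():
    rng = np.random.default_rng(11)
    x = rng.standard_normal(40)
    y = 1.2 * x + rng.standard_normal(40)
    a = org.rank_regression(y, pd.DataFrame({"x": x}))
    b = org.rank_regression(3.0 * y, pd.DataFrame({"x": x}))
    assert abs(b.params["x"] - 3.0 * a.params["x"]) < 1e-4


def test_rank_regression_errors(rng):
    x = rng.standard_normal(10)
    with pytest.raises(DegenerateDataError):  # rank-deficient
        org.rank_regression(x, pd.DataFrame({"a": x, "b": 2 * x}))
    with pytest.raises(SchemaError):
        org.rank_regression(x[:5], pd.DataFrame({"a": x}))


def test_age_adjusted_scan_overlap_logic(cohort, metabolome):
    score = cohort.latent  # stands in for the fitted score here
    sub = metabolome.human.iloc[:, :30]
    table = org.age_adjusted_metabolite_scan(sub, score, cohort.metadata["age"])
    overlap = table.attrs["n_overlap"]
    assert overlap <= min(table.attrs["n_sig_with_age"],
                          table.attrs["n_sig_without_age"])
    planted = {c for c, _ in syn.SyntheticConfig().planted_score_metabolites}
    hits = set(table.index[table["sig_without_age"]]) & planted
    assert len(hits) >= 5  # planted score-associated compounds are found
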