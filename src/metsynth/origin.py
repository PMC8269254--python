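"""Microbiome-origin attribution of plasma metabolites and rank regression.

Two independent prongs flag a compound as microbiome-associated:

* *producibility* — the compound is a single-step reaction product of some
  gene in the microbial gene set, via a gene -> reaction -> compound map
  (KEGG-orthology style); a host gene set can be mapped the same way so
  dual-origin compounds are visible;
* *gnotobiotic differential* — the compound differs between germfree and
  colonized mouse plasma (pooled-variance Student t on log intensities,
  BH FDR < 0.05, after removing compounds present in < 20% of samples).

A compound is microbiome-associated iff (producible OR differential) AND
present in the human plasma table.

Rank regression (for age-adjusted metabolite-vs-score scans) minimizes
Jaeckel's dispersion with Wilcoxon scores,

    D(b) = sum_i a(R(e_i)) e_i,   a(i) = sqrt(12) (i/(n+1) - 1/2),

which is equivalent to an L1 fit on all pairwise observation differences;
the intercept is the median residual, and coefficient inference uses the
asymptotic covariance tau^2 (Xc' Xc)^-1 with the tau scale estimated from
the density of pairwise residual differences at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.quantile_regression import QuantReg
from statsmodels.stats.multitest import multipletests

from metsynth.exceptions import DegenerateDataError, SchemaError
from metsynth.synthetic import MouseMetabolome, ReactionMap

MOUSE_MIN_PREVALENCE = 0.2
MOUSE_FDR_ALPHA = 0.05


def producible_compounds(gene_set: Iterable[str], reaction_map: ReactionMap,
                         transitive: bool = False) -> set[str]:
    """Compounds producible by the gene set: the union of product compounds
    over all reactions linked to any gene (single-step product logic).

    ``transitive=True`` additionally follows product -> substrate chains to
    reachable products (exploration mode, off by default).
    """
    genes = set(gene_set)
    unknown = genes - set(reaction_map.gene_reactions)
    if unknown:
        warnings.warn(f"{len(unknown)} unknown gene id(s) ignored")
    reactions = {r for g in genes & set(reaction_map.gene_reactions)
                 for r in reaction_map.gene_reactions[g]}
    products = {c for r in reactions for c in reaction_map.reactions[r]["products"]}
    if transitive:
        frontier = set(products)
        while frontier:
            reachable = {
                c for rid, rxn in reaction_map.reactions.items()
                if rid in reactions and set(rxn["substrates"]) & frontier
                for c in rxn["products"]}
            frontier = reachable - products
            products |= frontier
    return products


def mouse_differential(mouse: MouseMetabolome,
                       min_prevalence: float = MOUSE_MIN_PREVALENCE,
                       alpha: float = MOUSE_FDR_ALPHA,
                       log_transform: bool = True) -> tuple[set[str], pd.DataFrame]:
    """Germfree-vs-colonized differential compounds.

    Returns the set of compounds significant at BH q < alpha plus the full
    stats table. Aqueous and lipid fractions, when analyzed separately,
    are simply two calls on the corresponding sub-tables.
    """
    arms = mouse.design
    gf = arms.index[arms == "germfree"]
    col = arms.index[arms == "colonized"]
    if len(gf) < 2 or len(col) < 2:
        raise DegenerateDataError("need >= 2 mouse samples per arm")
    X = mouse.intensities
    prevalence = (X > 0).mean(axis=1)
    X = X.loc[prevalence >= min_prevalence]
    vals = np.log1p(X.to_numpy(dtype=float)) if log_transform else X.to_numpy(dtype=float)
    a = vals[:, [X.columns.get_loc(s) for s in gf]]
    b = vals[:, [X.columns.get_loc(s) for s in col]]
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    p = np.where(np.isnan(p), 1.0, p)
    table = pd.DataFrame({"t": t, "p": p}, index=X.index)
    table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    table["log2_fc"] = (b.mean(axis=1) - a.mean(axis=1)) / np.log(2.0)
    significant = set(table.index[table["q"] < alpha])
    return significant, table.sort_values("q")


def combine_origin(producible: Iterable[str], differential: Iterable[str],
                   human_compounds: Iterable[str],
                   host_producible: Iterable[str] | None = None) -> pd.DataFrame:
    """Per-compound origin flags over the union id space.

    ``microbiome_associated`` holds iff (producible OR differential) AND
    present in the human table; provenance records which prong(s) fired.
    """
    producible, differential = set(producible), set(differential)
    human = set(human_compounds)
    host = set(host_producible or ())
    compounds = sorted(producible | differential | human | host)
    rows = []
    for c in compounds:
        prod, diff, present = c in producible, c in differential, c in human
        provenance = "+".join(
            tag for tag, flag in (("producible", prod), ("mouse", diff)) if flag) or "none"
        rows.append({
            "compound": c,
            "producible_by_microbes": prod,
            "producible_by_host": c in host,
            "mouse_differential": diff,
            "present_in_human": present,
            "microbiome_associated": (prod or diff) and present,
            "provenance": provenance,
        })
    return pd.DataFrame(rows).set_index("compound")


# --------------------------------------------------------------------------
# rank-based (Wilcoxon score) linear regression


def _wilcoxon_dispersion(residuals: np.ndarray) -> float:
    """Jaeckel dispersion with Wilcoxon scores."""
    e = np.asarray(residuals, dtype=float)
    n = len(e)
    ranks = stats.rankdata(e)
    a = np.sqrt(12.0) * (ranks / (n + 1.0) - 0.5)
    return float(np.sum(a * e))


class RankRegression:
    """Rank-based linear model y ~ X with Wilcoxon scores.

    ``X`` may be a DataFrame or array of predictors (no intercept column; the
    intercept is the median residual and is reported separately).
    """

    def __init__(self, y, X):
        self.y = np.asarray(y, dtype=float)
        Xdf = pd.DataFrame(X)
        self.names = [str(c) for c in Xdf.columns]
        self.X = Xdf.to_numpy(dtype=float)
        n, p = self.X.shape
        if len(self.y) != n:
            raise SchemaError("y and X length mismatch")
        if np.isnan(self.y).any() or np.isnan(self.X).any():
            raise SchemaError("missing values not allowed")
        if n <= p + 2:
            raise DegenerateDataError("need n > p + 2")
        if np.linalg.matrix_rank(self.X - self.X.mean(axis=0)) < p:
            raise DegenerateDataError("rank-deficient design")

    def fit(self) -> "RankRegressionResults":
        n, p = self.X.shape
        i, j = np.triu_indices(n, k=1)
        dy = self.y[i] - self.y[j]
        dX = self.X[i] - self.X[j]
        # L1 fit on pairwise differences == Jaeckel/Wilcoxon minimizer
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            beta = QuantReg(dy, dX).fit(q=0.5, max_iter=5000).params
        residuals = self.y - self.X @ beta
        intercept = float(np.median(residuals))
        dispersion = _wilcoxon_dispersion(residuals)

        centered = self.X - self.X.mean(axis=0)
        tau = self._tau(residuals - intercept, p)
        cov = tau ** 2 * np.linalg.inv(centered.T @ centered)
        se = np.sqrt(np.diag(cov))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - p - 1)
        pvals = np.where(se == 0, 0.0, pvals)
        return RankRegressionResults(
            model=self, params=pd.Series(beta, index=self.names),
            intercept=intercept, bse=pd.Series(se, index=self.names),
            pvalues=pd.Series(pvals, index=self.names),
            dispersion=dispersion, tau=tau)

    @staticmethod
    def _tau(residuals: np.ndarray, p: int) -> float:
        """Scale tau = 1 / (sqrt(12) * integral f^2) from the density of
        pairwise residual differences at 0 (kernel estimate)."""
        n = len(residuals)
        i, j = np.triu_indices(n, k=1)
        diffs = residuals[i] - residuals[j]
        spread = np.std(diffs)
        if spread == 0:
            return 0.0
        g0 = float(stats.gaussian_kde(diffs)(0.0)[0])
        tau = 1.0 / (np.sqrt(12.0) * g0)
        return tau * np.sqrt(n / max(1.0, n - p - 1.0))


@dataclass
class RankRegressionResults:
    model: RankRegression
    params: pd.Series
    intercept: float
    bse: pd.Series
    pvalues: pd.Series
    dispersion: float
    tau: float

    def summary(self) -> str:
        lines = ["Rank-based regression (Wilcoxon scores)",
                 "=" * 40,
                 f"n: {len(self.model.y)}   dispersion at optimum: {self.dispersion:.4f}"
                 f"   tau: {self.tau:.4f}",
                 f"intercept (median residual): {self.intercept:.4f}",
                 "", f"{'term':<20} {'coef':>10} {'se':>10} {'p':>10}"]
        for name in self.params.index:
            lines.append(f"{name:<20} {self.params[name]:>10.4f} "
                         f"{self.bse[name]:>10.4f} {self.pvalues[name]:>10.4g}")
        return "\n".join(lines)


def rank_regression(y, X, include_age: bool = False,
                    age: Sequence[float] | None = None) -> RankRegressionResults:
    """Convenience wrapper; with ``include_age`` an age column is appended."""
    Xdf = pd.DataFrame(X)
    if include_age:
        if age is None:
            raise SchemaError("include_age=True requires the age vector")
        Xdf = Xdf.assign(age=np.asarray(age, dtype=float))
    return RankRegression(y, Xdf).fit()


def age_adjusted_metabolite_scan(metabolites: pd.DataFrame, score: pd.Series,
                                 age: pd.Series, alpha: float = 0.05) -> pd.DataFrame:
    """Rank-regress each metabolite on the score with and without age and
    compare the BH-significant sets (the with/without-age overlap report)."""
    rows = []
    for compound in metabolites.columns:
        y = metabolites[compound].to_numpy(dtype=float)
        without = rank_regression(y, pd.DataFrame({"score": score}))
        with_age = rank_regression(y, pd.DataFrame({"score": score}), include_age=True,
                                   age=age)
        rows.append({"compound": compound,
                     "coef_without_age": without.params["score"],
                     "p_without_age": without.pvalues["score"],
                     "coef_with_age": with_age.params["score"],
                     "p_with_age": with_age.pvalues["score"]})
    table = pd.DataFrame(rows).set_index("compound")
    for tag in ("without_age", "with_age"):
        table[f"q_{tag}"] = multipletests(table[f"p_{tag}"], method="fdr_bh")[1]
        table[f"sig_{tag}"] = table[f"q_{tag}"] < alpha
    both = int((table["sig_without_age"] & table["sig_with_age"]).sum())
    table.attrs["n_sig_without_age"] = int(table["sig_without_age"].sum())
    table.attrs["n_sig_with_age"] = int(table["sig_with_age"].sum())
    table.attrs["n_overlap"] = both
    return table
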