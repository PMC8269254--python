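# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices, and the limitations of `metsynth`. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Composite metabolic disease score

The score model z-scores the seven fasting markers (sample SD, ddof = 1),
takes PC1 of the covariance of the scaled matrix, orients the component so
triglycerides load positively (dyslipidemia/insulin-resistance markers then
load positively, HDL and adiponectin negatively), shifts the oriented
coordinates so the fitting panel's minimum maps to exactly 1, and applies a
natural log. The shifted coordinate is computed as `pc1 − min(pc1) + 1`
rather than `pc1 + shift` so the minimum subject scores exactly 0 in
floating point. The log base is a recorded model field; natural log was
chosen because the transform's base is not otherwise determined and `e`
keeps score differences interpretable as log-ratios of shifted PC1.

New subjects scored against a fitted model may fall below the fitting
panel's minimum; they legitimately score below 0 and are warned about, not
clamped. Subjects so far below that the shifted coordinate is non-positive
are an error — the model cannot score them.

The impairment cutoff regresses the score on each of the four markers with
well-established clinical thresholds and averages the four fitted values at
those thresholds. The triglyceride threshold (200 mg/dl) is the one the
score was designed around; glucose 100 mg/dl, HDL 40 mg/dl (unhealthy =
low) and LDL 160 mg/dl are conventional values and are configurable — they
are assumptions, not measured quantities. The default cutoff field is
populated with 1.4, the study-scale value of this construction; calling
`derive_cutoff` replaces it with the value the supplied panel implies.

The age model is OLS `score ~ age + cohort + age × cohort` with treatment
coding; per-cohort age slopes are reference slope + interaction, with
standard errors and p-values from the corresponding linear contrast.

## Synthetic cohort generator

One latent factor z ~ N(0, 1) per subject drives everything that should
correlate with metabolic health: each marker is
`mean + sd·(λ_m z + √(1−λ_m²) ε)` on its clinical scale, LBP gets loading
0.6, BMI a weak loading, and selected OTUs and metabolites load on z as
configured. Default marker loadings are strong (0.55–0.9 in magnitude)
because the score construction presumes a marker panel dominated by one
health axis; under these defaults PC1 recovers z (median correlation ≥ 0.9
at n = 150), which is the regime the downstream recovery tests certify.

Cohort sizes default to the five-cohort structure (22/32/14/20/25, total
113) and cohort-specific age distributions are normal with medians
33/34/34/46/60 years (SD 6): the treated cohorts are older, which is why
age enters the downstream models. Exact interquartile ranges are not
enforced.

OTU counts follow a logistic-normal/multinomial model: per-OTU baselines
μ_i ~ N(0, 1.2²), unit idiosyncratic noise, planted module blocks sharing a
factor at amplitude √(c/(1−c)) (giving within-block log-abundance
correlation c, default one 3-member block at c = 0.9), planted informative
OTUs adding `effect·z`, softmax closure, and multinomial sampling at
per-sample depths drawn from [19,986, 30,000] so the default rarefaction
depth is always usable. Planted informative OTUs share z and therefore
co-correlate near 0.39 — just above the module threshold — so they may
legitimately enter the selected set as a module rather than individually;
recovery checks account for module membership.

The metabolome bundle generates log-normal human intensities (10 of 200
compounds loading on z at 0.5 by default), a 2×8 germfree/colonized mouse
panel with 10 compounds shifted by 2 log2-fold, and a deterministic toy
gene→reaction→compound map built so the microbially producible set overlaps
the shifted set partially (dual-prong, single-prong and no-prong compounds
all exist) and a host gene set overlaps the microbial products, so
dual-origin flags are exercised.

What the generator does **not** emulate: real compositional overdispersion
(zero inflation beyond multinomial sampling), phylogenetic structure,
batch/run effects, missing data, nonlinear marker relationships, and
cohort-specific microbiome differences. Passing recovery tests therefore
demonstrate correctness of the estimators under the assumed generative
model, not robustness to everything real cohort data contains.

## SparCC and modules

SparCC uses the log-ratio variance matrix t_ij = Var log(x_i/x_j) and the
sparsity approximation: basis variances solve
`(p−1−d_i)ω_i² + Σ_{j∈partners(i)} ω_j² = Σ_j t_ij`, correlations are
`(ω_i²+ω_j²−t_ij)/(2ω_iω_j)` clipped to [−1, 1]. Zero handling defaults to
pseudocount 1 with a single deterministic estimate; Dirichlet-resampled
averaging (the original algorithm's stochastic variant) is available behind
a seed. Exclusion defaults are threshold 0.8 for 10 rounds, never stripping
a feature below two remaining partners; basis variances are floored at
1e−12 before the square root. At least 4 features are required for
identifiability.

Modules are maximal complete-linkage subtrees (distance 1 − r) in which
every pairwise correlation meets the threshold; the highest qualifying
ancestor wins, so modules are disjoint, and unqualified features remain
singletons. In r² mode (diet data) a pair qualifies only when r > 0 —
summing anti-correlated features is not meaningful. Summarization is
elementwise summation of member rows, conserving per-sample totals exactly.

Rarefaction subsamples without replacement via the multivariate
hypergeometric distribution; samples below depth are dropped with a
warning. The prevalence filter is strict (> 20% of samples).

## Forests, selection, permutation null

The forest is bagging over sklearn CART regression trees
(`min_samples_leaf = 5`, `mtry = ⌈p/3⌉`), with out-of-bag predictions,
OOB r² = 100·(1 − OOB-MSE/Var(y)), and OOB permutation importance (per
tree, MSE increase on OOB rows after permuting a feature; features unused
by a tree contribute 0 for that tree; the mean and SD across trees are
reported). Study-fidelity defaults are 500 trees and 25 thresholding
forests; the tests and pipeline run smaller forests (30–150 trees, 4–10
forests) because the recovery and null properties stabilize well below the
fidelity sizes — the documented problem sizes are a package choice.

Selection phases: (1) rank by mean importance over k forests; a
regularized CART (min split 20, min leaf 7, pruning proportional to the
curve's variance) is fitted to the importance-SD-vs-rank curve and features
with mean importance below the minimum fitted value are dropped;
(2) nested forests over ranked prefixes; keep the smallest prefix whose
mean OOB error is within one SD (across runs at the minimizer) of the
minimum; (3) stepwise addition of interpretation variables, kept when the
OOB error drops by more than the mean absolute error jump over the flat
tail of the interpretation curve. The nesting invariant
(prediction ⊆ interpretation ⊆ threshold ⊆ ranked) is asserted at
construction. On pure noise the interpretation set stays small (median ≤ 3
in the test conditions); forests on very few noise features carry an
intrinsic small-model OOB penalty, which is why the null floor is not
always a single variable.

The permutation null permutes the response B times (paper-fidelity
B = 1000, add-one p-value so p is never 0) and accepts any statistic
`stat(X, y, seed) → r²`. The default is the study's procedure — selection
followed by a standard forest on the interpretation set. A forest-only
statistic is provided for calibration studies and fast pipeline runs,
where B full selection runs per replicate would be disproportionate to the
question being asked; the calibration property (uniform p under the null)
is statistic-agnostic.

## Interaction forests

Iteration 1 is a standard forest. Later iterations sample, per tree, a
feature subset of size ⌈p/2⌉ without replacement with probabilities
`0.5·(normalized variance-reduction importance) + 0.5·uniform`, floored at
1/(10p). Variance-reduction (split) importance drives the reweighting
because it stays near-uniform on noise — every tree must split on
something — whereas OOB permutation importance degenerates to a few
chance-positive features and makes spurious concentration snowball. The
half-uniform mixing is the package's stabilization of the same effect; both
choices were fixed by the estimator's operating characteristics (planted
XOR interactions must clear the 0.30 prevalence threshold while pure noise
yields no edges) and are recorded here.

"Proximity" is parent–child adjacency of two *different* features among a
tree's internal nodes; a pair counts at most once per tree, so prevalence
(fraction of trees) is bounded by 1. Same-path but non-adjacent
co-occurrence is not counted — the narrower reading of "adjacent nodes".

## Networks and group tests

Spearman rho uses average ranks; two-sided p-values use the t
approximation on n−2 df (adequate at pipeline n; an exact mode is not
provided because pairs are corrected jointly anyway). BH correction is one
family over all tested pairs for networks and one family per supplied
feature set for outcome correlations; family membership is whatever table
the caller passes, and is therefore visible in the output.

Fisher r×c enumerates all tables with the observed margins (bounded by the
product of compositions; beyond the cap, a seeded Monte Carlo over
margin-preserving permutations), summing hypergeometric probabilities ≤
the observed one with a 1+1e−7 relative tolerance for float jitter.
All-zero rows/columns are dropped first. Kruskal–Wallis is tie-corrected
with a χ² p-value; fully tied data warn and return p = 1.

## Metabolite origin and rank regression

Producibility is single-step product membership under the map — the union
of product compounds over reactions linked to any queried gene — matching
the attribution tool the workflow emulates; a transitive-reachability mode
exists behind a flag, off by default. The mouse differential uses a
pooled-variance Student t (the named test) on log1p-transformed intensities
(standard for LC-MS; switchable), after removing compounds present in <20%
of samples, with BH q < 0.05. The combination rule
`(producible OR differential) AND present-in-human` is asserted per
compound, with provenance recording which prong fired.

Rank regression minimizes Jaeckel's dispersion with Wilcoxon scores
`a(i) = √12(i/(n+1) − ½)`, which is equivalent to L1 regression on all
pairwise observation differences and is solved by median (quantile)
regression on those differences. The intercept is the median residual.
Coefficient covariance is τ²(X_c′X_c)⁻¹ with τ = 1/(√12·ĝ(0)) estimated by
a Gaussian kernel density of pairwise residual differences at zero and a
√(n/(n−p−1)) degrees-of-freedom correction; p-values are two-sided t on
n−p−1 df. Exact-fit designs get τ = 0 and p = 0 by convention. Only the
Wilcoxon score function is implemented.

## Diversity

Shannon uses natural log over nonzero proportions; Pielou is H/ln(observed)
and is 0 (with a warning) for single-feature samples so degenerate
synthetic samples don't break pipelines. The Mantel test is Pearson on
upper-triangle distances (the classical statistic) with simultaneous
row/column permutation, two-sided add-one p, and an exact enumeration mode
for tiny n. Phylogeny-dependent metrics (Faith's PD, UniFrac) are out of
scope; Mantel operates on externally supplied matrices.

## Pipeline

`run_pipeline` chains the stages in study order with per-stage seeds
derived from one root seed, echoes every effective parameter into
`manifest.json`, and writes per-stage TSVs plus a report. The statistical
thresholds default to the study settings (depth 19,986; prevalence 0.2;
SparCC R 0.35; diet r² 0.75; FDR 0.25/0.1/0.05; interaction prevalence
0.30); forest sizes and the permutation count default to desk-scale values
(150 trees, 8 thresholding forests, B = 99 with the forest statistic) and
are raised to fidelity scale via the config. Selection runs on all
generated subjects; the emulated study restricted selection to the MSM
cohorts, a distinction without force here because the generator plants no
cohort-specific signal.

## Known limitations

* SparCC inference (bootstrap pseudo-p-values) is not implemented; only
  point estimates feed the module step, as in the emulated workflow.
* The Fisher r×c enumerator is exponential in principle; very large tables
  must use the Monte Carlo mode.
* Rank-regression τ estimation by KDE is simple and adequate at pipeline
  sample sizes but less refined than bandwidth-tuned proposals; p-values
  near exact fits are degenerate by construction.
* The permutation null at paper scale (B = 1000 full selection runs) is
  computationally heavy by design; nothing in the package approximates it
  silently — the fast statistic is an explicit, logged choice.
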