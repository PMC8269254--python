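"""End-to-end orchestration of the analysis stages.

Stage order mirrors the study design: (1) construct the metabolic health
outcome, (2) reduce the microbiome/diet layers (rarefaction, prevalence
filter, co-occurrence modules, summation), (3) select informative variables
by random forest with a permutation null, (4) relate selected variables to
each other and the outcome (Spearman/FDR networks, iterated-forest
interactions), (5) attribute plasma metabolites to the microbiome, plus
whole-community diversity checks.

One root seed drives every stage through named derived seeds; all effective
parameters are echoed into a machine-readable manifest so each stage can be
re-run independently.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import metsynth
from metsynth import diversity as div
from metsynth import interactions as ix
from metsynth import modules as mod
from metsynth import networks as net
from metsynth import origin as org
from metsynth import selection as sel
from metsynth import synthetic as syn
from metsynth.exceptions import InvalidConfigError
from metsynth.score import MetabolicScoreModel, age_cohort_model

log = logging.getLogger("metsynth.pipeline")


@dataclass
class PipelineConfig:
    """All stage thresholds (study-scale settings) plus run-scale knobs.

    The statistical thresholds are the study's; the forest sizes and
    permutation count default to desk-scale values that keep a full run in
    minutes — raise ``n_trees``/``n_threshold_forests``/``b_permutations``
    (study scale: 500 / 25 / 1000 with the selection statistic) for
    full-fidelity runs.
    """

    seed: int = 0
    rarefaction_depth: int = mod.RAREFACTION_DEPTH          # 19,986 reads
    prevalence_min_fraction: float = mod.PREVALENCE_MIN_FRACTION  # strict > 0.2
    sparcc_min_r: float = mod.SPARCC_MIN_R                  # 0.35
    diet_r2_cutoff: float = mod.DIET_R2_CUTOFF              # 0.75
    outcome_fdr: float = net.FDR_OUTCOME                    # 0.1
    network_fdr: float = net.FDR_NETWORK                    # 0.25
    metabolite_fdr: float = net.FDR_METABOLITE              # 0.05
    interaction_min_prevalence: float = ix.INTERACTION_PREVALENCE  # 0.30
    b_permutations: int = 99
    permutation_stat: str = "forest"     # "forest" (fast) or "selection" (study)
    n_trees: int = 150
    n_threshold_forests: int = 8
    n_interp_runs: int = 5
    synthetic: syn.SyntheticConfig = field(default_factory=syn.SyntheticConfig)

    def __post_init__(self) -> None:
        if not 0 < self.prevalence_min_fraction < 1:
            raise InvalidConfigError("prevalence fraction out of range")
        for name in ("outcome_fdr", "network_fdr", "metabolite_fdr"):
            if not 0 < getattr(self, name) < 1:
                raise InvalidConfigError(f"{name} out of range")
        if not 0 < self.interaction_min_prevalence <= 1:
            raise InvalidConfigError("interaction prevalence out of range")
        if self.permutation_stat not in ("forest", "selection"):
            raise InvalidConfigError("permutation_stat must be forest|selection")


def _stage_seed(root: int, stage: str) -> int:
    stages = ["score", "rarefy", "sparcc", "select", "null", "interactions",
              "mantel"]
    return int(np.random.SeedSequence((root, stages.index(stage)))
               .generate_state(1)[0] % (2**31 - 1))


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage on a synthetic cohort; returns the manifest dict and
    writes per-stage outputs + manifest + report under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scfg = config.synthetic
    cohort = syn.generate_cohort(scfg)
    counts = syn.generate_count_table(scfg)
    bundle = syn.generate_metabolome_and_map(scfg)
    report: list[str] = ["metsynth pipeline report", "=" * 40]

    # ---- stage 1: metabolic health outcome ------------------------------
    results = MetabolicScoreModel(cohort.markers).fit()
    cutoff = results.derive_cutoff()
    classified = results.classify()
    classified.to_csv(out / "scores.tsv", sep="\t")
    results.to_json(out / "score_model.json")
    agemod = age_cohort_model(classified["score"], cohort.metadata["age"],
                              cohort.metadata["cohort"])
    agemod.to_csv(out / "age_cohort_model.tsv", sep="\t")
    impaired = int((classified["class"] == "impaired").sum())
    report += [f"score: n={len(classified)}, cutoff={cutoff:.3f}, "
               f"impaired={impaired} ({100 * impaired / len(classified):.1f}%)"]

    # ---- stage 2: microbiome + diet reduction ---------------------------
    rarefied = mod.rarefy(counts, depth=config.rarefaction_depth,
                          seed=_stage_seed(config.seed, "rarefy"))
    filtered = mod.prevalence_filter(rarefied, config.prevalence_min_fraction)
    corr = mod.sparcc_correlation(filtered, seed=_stage_seed(config.seed, "sparcc"))
    microbe_modules = mod.smd_modules(corr, min_r=config.sparcc_min_r)
    summarized = mod.summarize_modules(filtered, microbe_modules)
    mod.modules_to_frame(microbe_modules).to_csv(out / "microbe_modules.tsv",
                                                 sep="\t", index=False)
    diet_corr = mod.pearson_correlation(cohort.diet)
    diet_modules = mod.smd_modules(diet_corr, min_r=config.diet_r2_cutoff,
                                   r_is_squared=True)
    diet_summarized = mod.summarize_modules(cohort.diet.T, diet_modules).T
    report += [f"microbiome: {filtered.shape[0]} OTUs after filters -> "
               f"{summarized.shape[0]} features "
               f"({len(microbe_modules.modules)} modules); "
               f"diet: {cohort.diet.shape[1]} -> {diet_summarized.shape[1]} "
               f"({len(diet_modules.modules)} modules)"]

    # ---- stage 3: variable selection ------------------------------------
    microbe_rel = (summarized / summarized.sum(axis=0)).T
    microbe_rel.columns = [f"microbe:{c}" for c in microbe_rel.columns]
    features = pd.concat([
        cohort.metadata[["age", "bmi", "bloating"]].astype(float),
        cohort.immune.add_prefix("immune:"),
        diet_summarized.add_prefix("diet:"),
        microbe_rel,
    ], axis=1)
    y = classified["score"]
    selection = sel.vsurf_select(
        features, y, seed=_stage_seed(config.seed, "select"),
        n_trees=config.n_trees, n_threshold_forests=config.n_threshold_forests,
        n_interp_runs=config.n_interp_runs)
    (out / "selection.json").write_text(json.dumps({
        "threshold_set": list(map(str, selection.threshold_set)),
        "interpretation_set": list(map(str, selection.interpretation_set)),
        "prediction_set": list(map(str, selection.prediction_set)),
        "threshold": selection.threshold}, indent=1))
    selection.importance.sort_values(ascending=False).to_csv(
        out / "importance.tsv", sep="\t", header=["importance"])
    stat = (sel.forest_r2_statistic(n_trees=config.n_trees)
            if config.permutation_stat == "forest"
            else sel.selection_r2_statistic(n_trees=config.n_trees,
                                            n_threshold_forests=config.n_threshold_forests,
                                            n_interp_runs=config.n_interp_runs))
    null = sel.permutation_null(features.loc[:, selection.interpretation_set], y,
                                B=config.b_permutations,
                                seed=_stage_seed(config.seed, "null"), stat=stat)
    report += [selection.summary(), null.summary()]

    # ---- stage 4: networks + interactions -------------------------------
    selected = features.loc[:, selection.interpretation_set]
    network = net.spearman_network(selected, fdr_threshold=config.network_fdr)
    network.edges_frame().to_csv(out / "network_edges.tsv", sep="\t", index=False)
    outcome = net.outcome_correlations(selected, y, fdr_threshold=config.outcome_fdr)
    outcome.to_csv(out / "outcome_correlations.tsv", sep="\t", index=False)
    graph = ix.iterative_forest_interactions(
        selected, y, n_trees=config.n_trees,
        min_prevalence=config.interaction_min_prevalence,
        seed=_stage_seed(config.seed, "interactions"))
    graph.edges_frame().to_csv(out / "interaction_edges.tsv", sep="\t", index=False)
    report += [f"network: {network.graph.number_of_edges()} edges at "
               f"FDR<{config.network_fdr}; "
               f"{int(outcome['significant'].sum())} outcome-correlated at "
               f"FDR<{config.outcome_fdr}; "
               f"{graph.graph.number_of_edges()} interaction edges at "
               f"prevalence>={config.interaction_min_prevalence}"]

    # ---- stage 5: metabolite origin -------------------------------------
    producible = org.producible_compounds(bundle.microbial_genes, bundle.reaction_map)
    host = org.producible_compounds(bundle.host_genes, bundle.reaction_map)
    differential, mouse_stats = org.mouse_differential(
        bundle.mouse, alpha=config.metabolite_fdr)
    origin = org.combine_origin(producible, differential, bundle.human.columns,
                                host_producible=host)
    origin.to_csv(out / "origin.tsv", sep="\t")
    met_outcome = net.outcome_correlations(bundle.human, y,
                                           fdr_threshold=config.metabolite_fdr)
    met_outcome.to_csv(out / "metabolite_correlations.tsv", sep="\t", index=False)
    assoc = set(origin.index[origin["microbiome_associated"]])
    sig_met = set(met_outcome.loc[met_outcome["significant"], "feature"])
    report += [f"origin: {len(producible)} producible, {len(differential)} mouse-"
               f"differential, {int(origin['microbiome_associated'].sum())} "
               f"microbiome-associated; {len(sig_met)} score-correlated "
               f"metabolites, {len(assoc & sig_met)} both"]

    # ---- stage 6: diversity ---------------------------------------------
    alpha = div.alpha_diversity(rarefied)
    alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
    adiv_corr = net.outcome_correlations(alpha[["shannon", "pielou"]], y)
    report += ["alpha diversity vs score: "
               + ", ".join(f"{r.feature} rho={r.rho:+.3f} (p={r.p:.3f})"
                           for r in adiv_corr.itertuples())]

    manifest = {
        "version": metsynth.__version__,
        "config": _config_dict(config),
        "stage_seeds": {s: _stage_seed(config.seed, s)
                        for s in ("score", "rarefy", "sparcc", "select", "null",
                                  "interactions", "mantel")},
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
        "summary": {
            "n_subjects": int(len(classified)),
            "cutoff": cutoff,
            "n_impaired": impaired,
            "n_microbe_modules": len(microbe_modules.modules),
            "n_interpretation": len(selection.interpretation_set),
            "n_prediction": len(selection.prediction_set),
            "observed_r2": null.observed_r2,
            "permutation_p": null.p,
            "n_network_edges": int(network.graph.number_of_edges()),
            "n_outcome_correlated": int(outcome["significant"].sum()),
            "n_interaction_edges": int(graph.graph.number_of_edges()),
            "n_microbiome_associated": int(origin["microbiome_associated"].sum()),
            "n_score_correlated_metabolites": len(sig_met),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out / "report.txt").write_text("\n".join(report) + "\n")
    log.info("pipeline complete: %s", out)
    return manifest


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["synthetic"]["n_per_cohort"] = dict(d["synthetic"]["n_per_cohort"])
    d["synthetic"]["latent_effect"] = dict(d["synthetic"]["latent_effect"])
    for key in ("planted_modules", "planted_informative",
                "planted_metabolite_shifts", "planted_score_metabolites"):
        d["synthetic"][key] = [list(t) for t in d["synthetic"][key]]
    return d
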