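"""Synthetic multi-omic cohort generator.

Emulates every data layer of a five-cohort metabolic-health study of
HIV-positive and high-risk MSM: fasting blood markers driven by a single
latent metabolic-health factor, a 21-analyte plasma immune panel whose first
analyte (LBP, lipopolysaccharide-binding protein) also loads on the latent
factor, 29 per-1,000-kcal diet features, an OTU count table with planted
co-occurring modules and planted score-informative taxa, a human plasma
metabolome, a germfree-vs-colonized mouse metabolome with planted shifts,
and a toy gene -> reaction -> compound map for producibility attribution.

The latent-factor model is deliberately minimal: one standard-normal z per
subject drives the markers (positive loadings for triglycerides, glucose,
insulin and leptin; negative for HDL and adiponectin), so the first
principal component of the marker panel is an estimate of z and the
composite score construction downstream is meaningful by design.

All randomness flows from one root seed through named substreams so each
layer can be regenerated independently and generators stay join-consistent
on subject ids.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from metsynth.exceptions import InvalidConfigError

MARKERS = ("triglycerides", "glucose", "insulin", "ldl", "hdl", "leptin", "adiponectin")

#: default loading of the latent metabolic factor on each marker (dyslipidemia
#: and insulin-resistance markers load positively, protective markers negatively)
DEFAULT_LATENT_EFFECT: Mapping[str, float] = {
    "triglycerides": 0.90,
    "glucose": 0.80,
    "insulin": 0.85,
    "ldl": 0.55,
    "hdl": -0.80,
    "leptin": 0.70,
    "adiponectin": -0.70,
}

#: marker (mean, sd) on their clinical scales (mg/dl except insulin uIU/ml,
#: leptin/adiponectin ng/ml and ug/ml)
MARKER_SCALES: Mapping[str, tuple[float, float]] = {
    "triglycerides": (130.0, 60.0),
    "glucose": (92.0, 12.0),
    "insulin": (10.0, 4.0),
    "ldl": (110.0, 30.0),
    "hdl": (50.0, 12.0),
    "leptin": (8.0, 4.0),
    "adiponectin": (10.0, 4.0),
}

#: five study cohorts with sizes echoing the cohort table (total 113)
DEFAULT_COHORTS: Mapping[str, int] = {
    "HIV-negative MSW": 22,
    "HIV-negative MSM": 32,
    "HIV-positive untreated": 14,
    "HIV-positive treated": 20,
    "HIV-positive treated LD": 25,
}

#: cohort median ages; treated cohorts are older (no age matching was feasible
#: in the emulated study, which is why age enters downstream models)
COHORT_AGE_MEDIANS: Mapping[str, float] = {
    "HIV-negative MSW": 33.0,
    "HIV-negative MSM": 34.0,
    "HIV-positive untreated": 34.0,
    "HIV-positive treated": 46.0,
    "HIV-positive treated LD": 60.0,
}

IMMUNE_ANALYTES = (
    "LBP", "sCD14", "sCD163", "FABP2", "IL-6", "IL-10", "TNF-a", "MCP-1",
    "IL-22", "SAA", "VCAM-1", "ICAM-1", "CRP", "GM-CSF", "IL-7", "IL-12",
    "IL-15", "IL-16", "IL-17A", "TNF-b", "VEGF",
)

_TAXA = ("Prevotella", "Coprococcus", "Dorea", "Blautia", "Bacteroides",
         "Oscillospira", "Faecalibacterium", "Ruminococcus", "Bifidobacterium",
         "Akkermansia")

# substream indices for named child seeds off the root SeedSequence
_STREAMS = {"latent": 0, "cohort": 1, "counts": 2, "metabolome": 3, "map": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Generator for a named substream of the root seed."""
    return np.random.default_rng(np.random.SeedSequence((seed, _STREAMS[stream])))


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study; defaults ARE the emulated conditions."""

    n_per_cohort: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_COHORTS))
    seed: int = 0
    latent_effect: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_LATENT_EFFECT))
    lbp_effect: float = 0.6
    n_otus: int = 60
    n_immune: int = 21
    n_diet: int = 29
    planted_modules: Sequence[tuple[int, float]] = ((3, 0.9),)
    planted_informative: Sequence[tuple[str, float]] = (
        ("OTU_0004", 0.8), ("OTU_0005", 0.8), ("OTU_0006", 0.8),
    )
    depth_range: tuple[int, int] = (19986, 30000)
    mouse_n_per_arm: int = 8
    n_metabolites: int = 200
    kegg_fraction: float = 0.4
    planted_metabolite_shifts: Sequence[tuple[str, float]] = tuple(
        (f"C{i:05d}", 2.0) for i in range(1, 11)
    )
    planted_score_metabolites: Sequence[tuple[str, float]] = tuple(
        (f"C{i:05d}", 0.5) for i in range(11, 21)
    )

    def __post_init__(self) -> None:
        if not self.n_per_cohort or any(n <= 0 for n in self.n_per_cohort.values()):
            raise InvalidConfigError("cohort sizes must be positive")
        for size, corr in self.planted_modules:
            if size < 2:
                raise InvalidConfigError("planted module needs >= 2 members")
            if not 0.0 < corr < 1.0:
                raise InvalidConfigError("within-module correlation must lie in (0, 1)")
        if sum(s for s, _ in self.planted_modules) > self.n_otus:
            raise InvalidConfigError("planted module members exceed n_otus")
        if min(self.n_otus, self.n_immune, self.n_diet, self.mouse_n_per_arm,
               self.n_metabolites) <= 0:
            raise InvalidConfigError("counts must be positive")
        if self.depth_range[0] < 1 or self.depth_range[0] > self.depth_range[1]:
            raise InvalidConfigError("invalid depth range")

    @property
    def n_subjects(self) -> int:
        return int(sum(self.n_per_cohort.values()))


@dataclass
class CohortData:
    """Generated subject-level tables, join-consistent on the subject index."""

    metadata: pd.DataFrame  # cohort, age, bmi, bloating
    markers: pd.DataFrame   # seven fasting markers
    immune: pd.DataFrame    # analyte panel, LBP first
    diet: pd.DataFrame      # per-1,000-kcal features
    latent: pd.Series       # the generating z, retained for validation


@dataclass
class CountTable:
    """Integer feature x sample abundance table."""

    counts: pd.DataFrame          # features x samples
    taxonomy: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique or not self.counts.columns.is_unique:
            raise InvalidConfigError("feature/sample ids must be unique")


@dataclass
class MouseMetabolome:
    """Compound x mouse-sample intensities with a germfree/colonized design."""

    intensities: pd.DataFrame
    design: pd.Series  # sample -> {"germfree", "colonized"}

    def __post_init__(self) -> None:
        counts = self.design.value_counts()
        if counts.get("germfree", 0) < 2 or counts.get("colonized", 0) < 2:
            raise InvalidConfigError("need >= 2 mouse samples per arm")


@dataclass
class ReactionMap:
    """gene -> reaction ids and reaction -> substrate/product compound ids."""

    gene_reactions: Mapping[str, Sequence[str]]
    reactions: Mapping[str, Mapping[str, Sequence[str]]]

    def __post_init__(self) -> None:
        for rid, rxn in self.reactions.items():
            if not rxn.get("products") or not rxn.get("substrates"):
                raise InvalidConfigError(f"reaction {rid} lacks substrates/products")


@dataclass
class MetabolomeBundle:
    human: pd.DataFrame            # subjects x compounds
    mouse: MouseMetabolome
    reaction_map: ReactionMap
    microbial_genes: tuple[str, ...]
    host_genes: tuple[str, ...]


def _subject_ids(config: SyntheticConfig) -> tuple[pd.Index, pd.Series]:
    labels = []
    for cohort, n in config.n_per_cohort.items():
        labels.extend([cohort] * n)
    ids = pd.Index([f"S{i:04d}" for i in range(1, len(labels) + 1)], name="subject")
    return ids, pd.Series(labels, index=ids, name="cohort")


def latent_factor(config: SyntheticConfig) -> pd.Series:
    """The per-subject latent metabolic-health factor z ~ N(0, 1).

    Drawn from its own substream so the marker, immune and OTU layers all see
    the same z without having to be generated together.
    """
    ids, _ = _subject_ids(config)
    z = _rng(config.seed, "latent").standard_normal(len(ids))
    return pd.Series(z, index=ids, name="z")


def generate_cohort(config: SyntheticConfig) -> CohortData:
    """Generate metadata, markers, immune and diet tables for all cohorts."""
    ids, cohort = _subject_ids(config)
    z = latent_factor(config)
    rng = _rng(config.seed, "cohort")
    n = len(ids)

    age = np.empty(n)
    for label in config.n_per_cohort:
        mask = (cohort == label).to_numpy()
        median = COHORT_AGE_MEDIANS.get(label, 40.0)
        age[mask] = np.clip(rng.normal(median, 6.0, mask.sum()), 20.0, 80.0)
    bmi = np.clip(25.0 + 2.0 * rng.standard_normal(n) + 0.5 * z.to_numpy(), 18.0, 30.0)
    bloating = np.clip(np.rint(1.0 + 0.5 * z.to_numpy()
                               + rng.standard_normal(n)), 0, 3).astype(int)
    metadata = pd.DataFrame(
        {"cohort": cohort, "age": np.round(age, 1), "bmi": np.round(bmi, 1),
         "bloating": bloating}, index=ids)

    markers = {}
    for name in MARKERS:
        loading = float(config.latent_effect.get(name, 0.0))
        if abs(loading) > 1.0:
            raise InvalidConfigError(f"|loading| > 1 for marker {name}")
        mean, sd = MARKER_SCALES[name]
        noise = np.sqrt(1.0 - loading ** 2) * rng.standard_normal(n)
        markers[name] = np.clip(mean + sd * (loading * z.to_numpy() + noise), 0.0, None)
    markers = pd.DataFrame(markers, index=ids)

    immune = {}
    for k, analyte in enumerate(IMMUNE_ANALYTES[: config.n_immune]):
        if analyte == "LBP":
            e = config.lbp_effect
            vals = 12.0 + 4.0 * (e * z.to_numpy()
                                 + np.sqrt(max(0.0, 1.0 - e ** 2)) * rng.standard_normal(n))
        else:
            vals = np.exp(rng.normal(np.log(5.0 + k), 0.5, n))
        immune[analyte] = np.clip(vals, 0.0, None)
    # pad with generic analytes if n_immune exceeds the named panel
    for k in range(len(IMMUNE_ANALYTES), config.n_immune):
        immune[f"analyte_{k}"] = np.exp(rng.normal(1.0, 0.5, n))
    immune = pd.DataFrame(immune, index=ids)

    diet_cols = ["fiber", "carotenoid", "lycopene"] + [
        f"diet_{k:02d}" for k in range(3, config.n_diet)]
    diet = pd.DataFrame(
        np.exp(rng.normal(1.5, 0.4, size=(n, config.n_diet))),
        index=ids, columns=diet_cols[: config.n_diet])

    return CohortData(metadata=metadata, markers=markers, immune=immune,
                      diet=diet, latent=z)


def generate_count_table(config: SyntheticConfig) -> CountTable:
    """OTU counts via a logistic-normal/multinomial compositional model.

    Planted modules share a latent component at the configured within-module
    log-abundance correlation; planted-informative OTUs additionally load on
    the cohort latent factor z. Per-sample depths are drawn at or above the
    rarefaction depth used downstream.
    """
    ids, _ = _subject_ids(config)
    z = latent_factor(config).to_numpy()
    rng = _rng(config.seed, "counts")
    p, n = config.n_otus, len(ids)

    otu_ids = [f"OTU_{i:04d}" for i in range(p)]
    mu = rng.normal(0.0, 1.2, p)
    log_a = mu[:, None] + rng.standard_normal((p, n))

    # planted co-occurring blocks occupy the leading OTU indices
    cursor = 0
    for size, corr in config.planted_modules:
        shared = rng.standard_normal(n)
        a = np.sqrt(corr / (1.0 - corr))
        log_a[cursor:cursor + size, :] += a * shared[None, :]
        cursor += size

    index = {oid: i for i, oid in enumerate(otu_ids)}
    for oid, effect in config.planted_informative:
        if oid not in index:
            raise InvalidConfigError(f"planted informative OTU {oid} unknown")
        log_a[index[oid], :] += effect * z

    props = np.exp(log_a - log_a.max(axis=0, keepdims=True))
    props /= props.sum(axis=0, keepdims=True)
    depths = rng.integers(config.depth_range[0], config.depth_range[1] + 1, n)
    counts = np.column_stack(
        [rng.multinomial(depths[j], props[:, j]) for j in range(n)])

    taxonomy = pd.Series(
        [f"{_TAXA[i % len(_TAXA)]} sp. {i:04d}" for i in range(p)],
        index=otu_ids, name="taxonomy")
    table = pd.DataFrame(counts, index=pd.Index(otu_ids, name="otu"), columns=ids)
    return CountTable(counts=table, taxonomy=taxonomy)


def generate_metabolome_and_map(config: SyntheticConfig) -> MetabolomeBundle:
    """Human + mouse metabolomes and a toy gene->reaction->compound map.

    The map is constructed so the microbially producible compound set and the
    germfree-vs-colonized shifted set overlap partially, mirroring the
    two-pronged attribution structure downstream.
    """
    ids, _ = _subject_ids(config)
    z = latent_factor(config).to_numpy()
    rng = _rng(config.seed, "metabolome")
    n, m = len(ids), config.n_metabolites

    n_kegg = int(round(config.kegg_fraction * m))
    compound_ids = [f"C{i:05d}" for i in range(1, n_kegg + 1)] + [
        f"UNK_{i:04d}" for i in range(1, m - n_kegg + 1)]
    known = set(compound_ids)
    for cid, _ in tuple(config.planted_metabolite_shifts) + tuple(
            config.planted_score_metabolites):
        if cid not in known:
            raise InvalidConfigError(f"planted effect references unknown compound {cid}")

    base = rng.normal(10.0, 1.0, m)  # log-intensity baselines
    human_log = base[None, :] + 0.8 * rng.standard_normal((n, m))
    score_eff = dict(config.planted_score_metabolites)
    for j, cid in enumerate(compound_ids):
        eff = score_eff.get(cid)
        if eff:
            human_log[:, j] = base[j] + 0.8 * (
                eff * z + np.sqrt(1 - eff ** 2) * rng.standard_normal(n))
    human = pd.DataFrame(np.exp(human_log), index=ids, columns=compound_ids)

    # mouse panel: most human compounds plus some mouse-only ones
    n_shared = int(round(0.8 * m))
    mouse_compounds = compound_ids[:n_shared] + [f"MOUSE_{i:04d}" for i in range(1, 31)]
    k = config.mouse_n_per_arm
    samples = [f"GF_{i}" for i in range(1, k + 1)] + [f"HUM_{i}" for i in range(1, k + 1)]
    design = pd.Series(["germfree"] * k + ["colonized"] * k,
                       index=samples, name="arm")
    mouse_base = rng.normal(10.0, 1.0, len(mouse_compounds))
    mouse_log = mouse_base[:, None] + 0.5 * rng.standard_normal(
        (len(mouse_compounds), 2 * k))
    shift = dict(config.planted_metabolite_shifts)
    for i, cid in enumerate(mouse_compounds):
        lfc = shift.get(cid)
        if lfc:
            mouse_log[i, k:] += lfc * np.log(2.0)
    mouse = MouseMetabolome(
        intensities=pd.DataFrame(np.exp(mouse_log), index=mouse_compounds,
                                 columns=samples),
        design=design)

    reaction_map, microbial, host = _toy_reaction_map(config)
    return MetabolomeBundle(human=human, mouse=mouse, reaction_map=reaction_map,
                            microbial_genes=microbial, host_genes=host)


def _toy_reaction_map(config: SyntheticConfig):
    """Deterministic toy map: microbial genes produce KEGG compounds that
    partially overlap the planted mouse shifts; host genes produce a
    partially overlapping set so dual-origin compounds exist."""
    rng = _rng(config.seed, "map")
    n_kegg = int(round(config.kegg_fraction * config.n_metabolites))
    kegg = [f"C{i:05d}" for i in range(1, n_kegg + 1)]
    shifted = [cid for cid, _ in config.planted_metabolite_shifts if cid in set(kegg)]
    others = [c for c in kegg if c not in set(shifted)]
    rng.shuffle(others)
    # microbial products: half the shifted compounds plus unshifted ones
    microbial_products = shifted[: len(shifted) // 2] + others[:15]
    host_products = others[10:25]  # overlaps microbial products on others[10:15]

    gene_reactions: dict[str, list[str]] = {}
    reactions: dict[str, dict[str, list[str]]] = {}
    rid = 1
    for prefix, products in (("K", microbial_products), ("HSA", host_products)):
        for b in range(0, len(products), 3):
            batch = products[b:b + 3]
            rname = f"R{rid:05d}"
            rid += 1
            reactions[rname] = {"substrates": ["C99999"], "products": list(batch)}
            gene = f"{prefix}{(b // 3) + 1:05d}"
            gene_reactions.setdefault(gene, []).append(rname)
    microbial = tuple(g for g in gene_reactions if g.startswith("K"))
    host = tuple(g for g in gene_reactions if g.startswith("HSA"))
    return ReactionMap(gene_reactions=gene_reactions, reactions=reactions), microbial, host


def write_layers(config: SyntheticConfig, out_dir: str | Path) -> dict[str, str]:
    """Write every generated layer as TSV/JSON under ``out_dir``.

    Returns a manifest of relative file names.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config)
    counts = generate_count_table(config)
    bundle = generate_metabolome_and_map(config)

    files = {}
    for name, df in (("metadata", cohort.metadata), ("markers", cohort.markers),
                     ("immune", cohort.immune), ("diet", cohort.diet)):
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t")
        files[name] = path.name
    counts.counts.to_csv(out / "otu_counts.tsv", sep="\t")
    files["otu_counts"] = "otu_counts.tsv"
    if counts.taxonomy is not None:
        counts.taxonomy.to_csv(out / "taxonomy.tsv", sep="\t")
        files["taxonomy"] = "taxonomy.tsv"
    bundle.human.to_csv(out / "human_metabolites.tsv", sep="\t")
    files["human_metabolites"] = "human_metabolites.tsv"
    bundle.mouse.intensities.to_csv(out / "mouse_metabolites.tsv", sep="\t")
    bundle.mouse.design.to_csv(out / "mouse_design.tsv", sep="\t")
    files["mouse_metabolites"] = "mouse_metabolites.tsv"
    files["mouse_design"] = "mouse_design.tsv"
    with open(out / "reaction_map.json", "w") as fh:
        json.dump({"gene_reactions": dict(bundle.reaction_map.gene_reactions),
                   "reactions": dict(bundle.reaction_map.reactions),
                   "microbial_genes": list(bundle.microbial_genes),
                   "host_genes": list(bundle.host_genes)}, fh, indent=1)
    files["reaction_map"] = "reaction_map.json"
    return files
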