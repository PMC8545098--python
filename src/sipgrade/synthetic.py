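"""Synthetic SIP communities with known enrichment truth.

Generates everything the downstream analysis consumes — taxa, contig
sequences, per-fraction depth tables in the jgi layout, functional
annotation tables, labelled classifier training sets and toy
genome-scale metabolic models — with the statistical structure the
method assumes: GC-dependent band migration, partial/complete ¹³C
labelling (including bimodal mixed populations) and overdispersed
(negative-binomial) count noise.

The class-conditional parameter ranges were chosen so that each
enrichment class places detectable mass inside the sequenced window
F6–F13: the window spans only ~0.037 g ml⁻¹ of buoyant density, which is
comparable to the full-label shift, so unenriched DNA is visible there
only when GC-rich — exactly the GC confounding the null profiles control
for.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._taxa import LINEAGES
from .features import ObservedProfile, extract_features
from .gradient import (
    DEFAULT_L0,
    DEFAULT_SIGMA0,
    FractionLayout,
    LabelState,
    bd_mixture,
    build_layout,
    expected_profile,
    simulate_null_profile,
)

#: Enrichment classes in fixed (tie-break) order.
CLASSES: tuple[str, ...] = ("strong", "weak", "unenriched", "bimodal", "undetermined")

DEFAULT_CLASS_MIX: dict[str, float] = {
    "strong": 0.30,
    "weak": 0.10,
    "unenriched": 0.35,
    "bimodal": 0.15,
    "undetermined": 0.10,
}


class ConfigError(ValueError):
    pass


@dataclass
class BenchmarkConfig:
    """Study conditions of the synthetic benchmark.

    Defaults: 50× mean sequencing depth, negative-binomial dispersion
    0.5 (variance μ + μ²/0.5 — strongly overdispersed, as is typical of
    metagenomic coverage), log-normal contig lengths truncated at
    2,500 bp, and a 600-example training set whose class mix is
    30/10/35/15/10 % strong/weak/unenriched/bimodal/undetermined.
    """

    n_taxa: int = 30
    class_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    sequencing_depth: float = 50.0
    nb_dispersion: float = 0.5
    length_meanlog: float = 8.7  # median contig ~6 kb
    length_sdlog: float = 0.6
    min_contig_length: int = 2500
    sigma0: float = DEFAULT_SIGMA0
    l0: float = DEFAULT_L0
    n_training: int = 600
    holdout_fraction: float = 0.20
    # truth-rule thresholds (g/ml BD shift; X coverage)
    weak_shift_lo: float = 0.005
    weak_shift_hi: float = 0.02
    min_window_depth: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("class_mix must sum to 1")
        if set(self.class_mix) - set(CLASSES):
            raise ConfigError(f"unknown classes in mix: {set(self.class_mix) - set(CLASSES)}")
        if self.min_contig_length < 2500:
            raise ConfigError("minimum contig length is 2,500 bp")


@dataclass
class TaxonSpec:
    taxon_id: str
    lineage: tuple[str, ...]  # domain..species, 7 ranks
    genome_size: int
    gc_mean: float
    gc_sd: float
    abundance: float
    label: LabelState
    enrichment_class: str
    cellulolytic: bool
    annotations: dict[tuple[str, str], int] = field(default_factory=dict)
    model_id: str | None = None

    @property
    def order(self) -> str:
        return self.lineage[3]


def true_class(
    label: LabelState,
    expected_window_depth: float,
    *,
    min_window_depth: float = 3.0,
    weak_shift_lo: float = 0.005,
    weak_shift_hi: float = 0.02,
) -> str:
    """Deterministic ground-truth enrichment class of a label state.

    A contig whose expected mean depth across the sequenced window falls
    below ``min_window_depth`` is undetermined regardless of labelling;
    a split population (0.2 ≤ w ≤ 0.6) at high excess is bimodal; a
    mostly labelled population (w ≥ 0.8) at high excess is strong;
    otherwise the population's mean BD shift decides weak vs unenriched,
    with any residual large-shift state read as strong.
    """
    if expected_window_depth < min_window_depth:
        return "undetermined"
    w, ae = label.labeled_fraction, label.atom_excess
    if 0.2 <= w <= 0.6 and ae >= 0.5:
        return "bimodal"
    if w >= 0.8 and ae >= 0.5:
        return "strong"
    shift = label.mean_bd_shift
    if weak_shift_lo <= shift <= weak_shift_hi:
        return "weak"
    if shift < weak_shift_lo:
        return "unenriched"
    return "strong"


# ---------------------------------------------------------------------------
# class-conditional parameter sampling

#: Probability that a taxon of each class carries endoglucanase genes.
P_CELLULOLYTIC: dict[str, float] = {
    "strong": 0.6,
    "weak": 0.25,
    "unenriched": 0.3,
    "bimodal": 0.5,
    "undetermined": 0.3,
}


def _sample_label_params(rng, cls: str) -> tuple[float, float, float, float]:
    """Draw (gc, atom_excess, labeled_fraction, abundance) for one class.

    Labelled classes sit where their band lands inside the sequenced
    window; unenriched taxa are GC-rich (the only unlabelled DNA dense
    enough to be sequenced); undetermined taxa are rare members whose
    coverage falls below the callable floor.
    """
    if cls == "strong":
        gc = float(np.clip(rng.normal(0.48, 0.04), 0.40, 0.58))
        ae = rng.uniform(0.65, 0.85)
        w = rng.uniform(0.85, 1.0)
        ab = rng.uniform(0.8, 1.6)
    elif cls == "weak":
        gc = float(np.clip(rng.normal(0.62, 0.03), 0.56, 0.70))
        ae = rng.uniform(0.16, 0.44)
        w = 1.0
        ab = rng.uniform(0.8, 1.6)
    elif cls == "unenriched":
        gc = float(np.clip(rng.normal(0.67, 0.025), 0.62, 0.74))
        ae, w = 0.0, 0.0
        ab = rng.uniform(0.8, 1.6)
    elif cls == "bimodal":
        gc = float(np.clip(rng.normal(0.60, 0.02), 0.57, 0.63))
        ae = rng.uniform(0.70, 0.85)
        w = rng.uniform(0.25, 0.55)
        ab = rng.uniform(0.8, 1.6)
    elif cls == "undetermined":
        gc = float(np.clip(rng.normal(0.60, 0.06), 0.45, 0.75))
        ae, w = 0.0, 0.0
        ab = rng.uniform(0.01, 0.30)
    else:
        raise ConfigError(f"unknown class {cls!r}")
    return gc, ae, w, ab


def expected_window_depth(
    p_full: np.ndarray, layout: FractionLayout, depth: float, abundance: float
) -> float:
    """Expected mean coverage across the sequenced window."""
    return depth * abundance * float(np.mean(p_full[layout.window_slice]))


# ---------------------------------------------------------------------------
# community & contigs


def generate_community(
    config: BenchmarkConfig, seed: int, layout: FractionLayout | None = None
) -> list[TaxonSpec]:
    """Sample a community of taxa realizing the configured class mix."""
    layout = layout or build_layout()
    rng = np.random.default_rng(seed)
    classes = sorted(config.class_mix)
    probs = np.array([config.class_mix[c] for c in classes])
    taxa = []
    lineage_order = rng.permutation(len(LINEAGES))
    for i in range(config.n_taxa):
        cls = classes[rng.choice(len(classes), p=probs)]
        lineage = LINEAGES[lineage_order[i % len(LINEAGES)]]
        spec = _sample_taxon(rng, cls, lineage, f"tax{i:03d}", config, layout)
        taxa.append(spec)
    return taxa


def _sample_taxon(
    rng, cls: str, lineage, taxon_id: str, config: BenchmarkConfig, layout: FractionLayout
) -> TaxonSpec:
    # rejection-sample until the deterministic truth rule confirms the class
    for _ in range(1000):
        gc, ae, w, ab = _sample_label_params(rng, cls)
        label = LabelState(ae, w)
        mix = bd_mixture(gc, 10_000, label, sigma0=config.sigma0, l0=config.l0)
        p = expected_profile(mix, layout)
        wd = expected_window_depth(p, layout, config.sequencing_depth, ab)
        got = true_class(
            label, wd,
            min_window_depth=config.min_window_depth,
            weak_shift_lo=config.weak_shift_lo,
            weak_shift_hi=config.weak_shift_hi,
        )
        if got == cls:
            break
    else:  # pragma: no cover - parameter ranges make this unreachable
        raise ConfigError(f"could not realize class {cls!r}")
    cellulolytic = rng.random() < P_CELLULOLYTIC[cls]
    spec = TaxonSpec(
        taxon_id=taxon_id,
        lineage=lineage,
        genome_size=int(rng.uniform(3e6, 8e6)),
        gc_mean=gc,
        gc_sd=0.015,
        abundance=ab,
        label=label,
        enrichment_class=cls,
        cellulolytic=cellulolytic,
    )
    spec.annotations = _sample_annotations(rng, cellulolytic)
    return spec


# family pools for the annotation generator (Poisson means per family)
_ENDOGLUCANASE_POOL = ["GH9", "GH5_1", "GH5_2", "GH6", "GH8", "GH12", "GH45", "GH48", "AA10", "AA9"]
_OTHER_FEATURES: list[tuple[str, str, float]] = [
    ("SM", "t1pks", 1.5),
    ("SM", "bacteriocin", 1.0),
    ("SM", "nrps", 0.8),
    ("SM", "terpene", 0.7),
    ("peptidase", "M23", 2.0),
    ("peptidase", "S08", 1.5),
    ("CBM", "CBM2", 1.0),
    ("CBM", "CBM6", 0.8),
    ("chitinase", "GH18", 0.8),
    ("chitinase", "GH19", 0.4),
    ("motility", "flagellum", 0.6),
    ("adhesion", "tad", 0.5),
]


def _sample_annotations(rng, cellulolytic: bool) -> dict[tuple[str, str], int]:
    ann: dict[tuple[str, str], int] = {}
    if cellulolytic:
        fams = rng.choice(len(_ENDOGLUCANASE_POOL), size=rng.integers(1, 4), replace=False)
        for k in fams:
            fam = _ENDOGLUCANASE_POOL[k]
            cls = "AA" if fam.startswith("AA") else "GH"
            ann[(cls, fam)] = int(rng.integers(1, 6))
    for cls, fam, mean in _OTHER_FEATURES:
        n = int(rng.poisson(mean))
        if n > 0:
            ann[(cls, fam)] = n
    return ann


def _draw_contig_lengths(rng, genome_size: int, config: BenchmarkConfig) -> list[int]:
    lengths: list[int] = []
    total = 0
    while total < genome_size:
        L = int(max(config.min_contig_length, round(rng.lognormal(config.length_meanlog, config.length_sdlog))))
        if total + L > genome_size:
            L = max(config.min_contig_length, genome_size - total)
        lengths.append(L)
        total += L
    return lengths


def generate_contigs(
    taxa: list[TaxonSpec], config: BenchmarkConfig, seed: int
) -> tuple[list, pd.DataFrame]:
    """Contig sequences plus the per-contig truth table.

    Lengths are log-normal truncated at the 2,500 bp assembly cutoff and
    sum to the taxon's genome size (within one minimum contig length);
    base composition is constructed to match the drawn GC exactly (to
    rounding), then shuffled.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    rng = np.random.default_rng(seed)
    records, rows = [], []
    for taxon in taxa:
        for j, L in enumerate(_draw_contig_lengths(rng, taxon.genome_size, config)):
            gc = float(np.clip(rng.normal(taxon.gc_mean, taxon.gc_sd), 0.01, 0.99))
            n_gc = int(round(gc * L))
            gc_part = rng.choice(list("GC"), size=n_gc)
            at_part = rng.choice(list("AT"), size=L - n_gc)
            seq = np.concatenate([gc_part, at_part])
            rng.shuffle(seq)
            cid = f"{taxon.taxon_id}_c{j:04d}"
            records.append(SeqRecord(Seq("".join(seq)), id=cid, description=""))
            rows.append(
                {
                    "contig_id": cid,
                    "taxon_id": taxon.taxon_id,
                    "order": taxon.order,
                    "length": L,
                    "gc": n_gc / L,
                    "atom_excess": taxon.label.atom_excess,
                    "labeled_fraction": taxon.label.labeled_fraction,
                    "abundance": taxon.abundance,
                    "true_class": taxon.enrichment_class,
                }
            )
    return records, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# depth & annotation tables


def _nb_draw(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with mean μ and variance μ + α·μ².

    ``dispersion`` is the quadratic overdispersion coefficient α (the
    DESeq2/edgeR convention), i.e. the NB size parameter is 1/α.
    """
    mean = np.asarray(mean, dtype=float)
    out = np.zeros_like(mean)
    pos = mean > 0
    size = 1.0 / dispersion
    p = size / (size + mean[pos])
    out[pos] = rng.negative_binomial(size, p)
    return out


def generate_depth_table(
    truth: pd.DataFrame,
    layout: FractionLayout,
    config: BenchmarkConfig,
    seed: int,
    path=None,
) -> pd.DataFrame:
    """Per-contig depth table in the jgi_summarize_bam_contig_depths layout.

    The expected depth of contig c in window fraction f is
    depth × abundance × p_cf with p_cf from the contig's expected
    gradient profile; observed depths are negative-binomial draws around
    that mean, one depth and one variance column per fraction.
    """
    rng = np.random.default_rng(seed)
    window = list(layout.sequenced_window)
    rows = []
    for rec in truth.itertuples(index=False):
        label = LabelState(rec.atom_excess, rec.labeled_fraction)
        mix = bd_mixture(rec.gc, rec.length, label, sigma0=config.sigma0, l0=config.l0)
        p = expected_profile(mix, layout)[layout.window_slice]
        mu = config.sequencing_depth * rec.abundance * p
        depths = _nb_draw(rng, mu, config.nb_dispersion)
        var = mu + config.nb_dispersion * mu**2
        row = {"contigName": rec.contig_id, "contigLen": rec.length, "totalAvgDepth": depths.sum()}
        for f, d, v in zip(window, depths, var):
            row[f"F{f}"] = d
            row[f"F{f}-var"] = v
        rows.append(row)
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return df


def generate_annotation_table(taxa: list[TaxonSpec], path=None) -> pd.DataFrame:
    """Long-format annotation counts: unit_id, feature_class, family, count."""
    rows = [
        {"unit_id": t.taxon_id, "feature_class": cls, "family": fam, "count": n}
        for t in taxa
        for (cls, fam), n in sorted(t.annotations.items())
    ]
    df = pd.DataFrame(rows, columns=["unit_id", "feature_class", "family", "count"])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def taxonomy_table(truth: pd.DataFrame, taxa: list[TaxonSpec], path=None) -> pd.DataFrame:
    lineages = {t.taxon_id: ";".join(t.lineage) for t in taxa}
    df = pd.DataFrame(
        {"contig_id": truth["contig_id"], "lineage": truth["taxon_id"].map(lineages)}
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


# ---------------------------------------------------------------------------
# training set


def _stratified_counts(n: int, mix: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n examples over the class mix."""
    raw = {c: n * p for c, p in mix.items()}
    counts = {c: int(math.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    for c in sorted(raw, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    return counts


def generate_training_set(
    config: BenchmarkConfig, seed: int, layout: FractionLayout | None = None
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Labelled feature set for classifier training.

    Returns (features, labels, truth): ``config.n_training`` contig
    profiles (default 600) stratified over the class mix, each passed
    through the same feature extraction as observed data.
    """
    layout = layout or build_layout()
    rng = np.random.default_rng(seed)
    counts = _stratified_counts(config.n_training, config.class_mix)
    feat_rows, labels, truth_rows = [], [], []
    i = 0
    for cls in CLASSES:
        for _ in range(counts.get(cls, 0)):
            cid = f"train{i:04d}"
            i += 1
            L = int(max(config.min_contig_length, round(rng.lognormal(config.length_meanlog, config.length_sdlog))))
            for _ in range(1000):
                gc, ae, w, ab = _sample_label_params(rng, cls)
                label = LabelState(ae, w)
                mix = bd_mixture(gc, L, label, sigma0=config.sigma0, l0=config.l0)
                p = expected_profile(mix, layout)
                wd = expected_window_depth(p, layout, config.sequencing_depth, ab)
                if true_class(
                    label, wd,
                    min_window_depth=config.min_window_depth,
                    weak_shift_lo=config.weak_shift_lo,
                    weak_shift_hi=config.weak_shift_hi,
                ) == cls:
                    break
            else:  # pragma: no cover
                raise ConfigError(f"could not realize class {cls!r}")
            mu = config.sequencing_depth * ab * p[layout.window_slice]
            depths = _nb_draw(rng, mu, config.nb_dispersion)
            obs = ObservedProfile(contig_id=cid, depths=depths, total_depth=float(depths.sum()), length=L, gc=gc)
            null = simulate_null_profile(gc, L, layout, sigma0=config.sigma0, l0=config.l0)
            feat_rows.append(extract_features(obs, null[layout.window_slice]))
            labels.append(cls)
            truth_rows.append(
                {"contig_id": cid, "length": L, "gc": gc, "atom_excess": ae,
                 "labeled_fraction": w, "abundance": ab, "true_class": cls}
            )
    features = pd.DataFrame(feat_rows)
    return features, pd.Series(labels, index=features.index, name="true_class"), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# toy metabolic models

#: 32-slot target compound list: the 20 proteinogenic amino acids plus
#: common cofactors/vitamins and nucleotide precursors.
TARGET_COMPOUNDS: tuple[str, ...] = (
    "ala", "arg", "asn", "asp", "cys", "gln", "glu", "gly", "his", "ile",
    "leu", "lys", "met", "phe", "pro", "ser", "thr", "trp", "tyr", "val",
    "thf", "nad", "fad", "coa", "pydx", "thm", "ribflv", "btn",
    "heme", "q8", "amp", "gmp",
)

PATHWAY_STATUSES = ("complete", "deleted", "gapfilled")


def build_toy_model(model_id: str, statuses: dict[str, str]) -> dict:
    """One toy genome-scale model with per-compound pathway statuses.

    Each target compound gets a two-step biosynthesis pathway from the
    central precursor (``complete``), the same pathway flagged as
    gap-filled (``gapfilled``), or no pathway at all (``deleted``).
    Biomass requires every target; the rich medium supplies all targets
    by exchange, the minimal medium supplies only the carbon source plus
    the compounds this genome cannot make (its essential nutrients).
    """
    targets = list(statuses)
    compounds = [
        {"id": "glc", "name": "glucose", "is_biomass_precursor": False, "is_target_compound": False},
        {"id": "cc", "name": "central precursor", "is_biomass_precursor": True, "is_target_compound": False},
    ]
    reactions = [
        {
            "id": "R_central",
            "stoichiometry": {"glc": -1, "cc": 1},
            "lower_bound": 0, "upper_bound": 1000,
            "gapfilled": False, "central_carbon": True,
        }
    ]
    biomass_stoich: dict[str, float] = {"cc": -1}
    exchange_ids = ["EX_glc"]
    reactions.append(
        {"id": "EX_glc", "stoichiometry": {"glc": -1}, "lower_bound": 0,
         "upper_bound": 1000, "gapfilled": False, "central_carbon": False}
    )
    rich: dict[str, list[float]] = {"EX_glc": [-10, 1000]}
    minimal: dict[str, list[float]] = {"EX_glc": [-10, 1000]}
    for cpd in targets:
        status = statuses[cpd]
        compounds.append(
            {"id": cpd, "name": cpd, "is_biomass_precursor": True, "is_target_compound": True}
        )
        biomass_stoich[cpd] = -1
        ex_id = f"EX_{cpd}"
        exchange_ids.append(ex_id)
        reactions.append(
            {"id": ex_id, "stoichiometry": {cpd: -1}, "lower_bound": 0,
             "upper_bound": 1000, "gapfilled": False, "central_carbon": False}
        )
        rich[ex_id] = [-10, 1000]
        if status == "deleted":
            minimal[ex_id] = [-10, 1000]  # essential nutrient for this genome
            continue
        gap = status == "gapfilled"
        inter = f"pre_{cpd}"
        compounds.append(
            {"id": inter, "name": inter, "is_biomass_precursor": False, "is_target_compound": False}
        )
        reactions.append(
            {"id": f"R_{cpd}_1", "stoichiometry": {"cc": -1, inter: 1},
             "lower_bound": 0, "upper_bound": 1000, "gapfilled": gap, "central_carbon": False}
        )
        reactions.append(
            {"id": f"R_{cpd}_2", "stoichiometry": {inter: -1, cpd: 1},
             "lower_bound": 0, "upper_bound": 1000, "gapfilled": gap, "central_carbon": False}
        )
    reactions.append(
        {"id": "biomass", "stoichiometry": biomass_stoich, "lower_bound": 0,
         "upper_bound": 1000, "gapfilled": False, "central_carbon": False}
    )
    return {
        "id": model_id,
        "compounds": compounds,
        "reactions": reactions,
        "biomass_reaction": "biomass",
        "exchange_reactions": exchange_ids,
        "media": {"rich": rich, "minimal": minimal},
        "target_compounds": targets,
    }


def generate_toy_models(
    n_models: int = 3, n_targets: int = 32, seed: int = 0
) -> list[tuple[dict, dict[str, str]]]:
    """Toy models with known auxotrophy truth.

    Returns (model, truth) pairs where truth maps each target compound
    to its pathway status; ``complete`` is the prototrophic case, both
    ``deleted`` and ``gapfilled`` are auxotrophic under the default
    thresholds (θ=1, γ=0).
    """
    if not 1 <= n_targets <= len(TARGET_COMPOUNDS):
        raise ConfigError(f"n_targets must be in [1, {len(TARGET_COMPOUNDS)}]")
    rng = np.random.default_rng(seed)
    out = []
    targets = TARGET_COMPOUNDS[:n_targets]
    for m in range(n_models):
        statuses = {
            cpd: PATHWAY_STATUSES[rng.integers(0, 3)] for cpd in targets
        }
        out.append((build_toy_model(f"toy{m:02d}", statuses), statuses))
    return out
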