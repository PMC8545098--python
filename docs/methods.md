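# Methods

`sipgrade` implements a gradient-resolved DNA stable-isotope-probing
(SIP) analysis: per-contig read-depth profiles across CsCl gradient
fractions are compared with GC-matched natural-abundance null profiles,
classified into five ¹³C-enrichment categories with a random forest,
aggregated into phylobins, and carried into ecogenomic trait
comparisons. This note documents the models, parameters and design
choices, and what the synthetic benchmark does and does not establish.

## Gradient physics

DNA bands in a CsCl equilibrium gradient at a buoyant density (BD)
determined by base and isotopic composition. We use the Schildkraut-type
linear relation

    BD(GC, E) = 1.660 + 0.098·GC + 0.036·E   [g ml⁻¹]

where GC is the G+C fraction and E the ¹³C atom-fraction excess above
the ~1.1 % natural abundance (E ≤ 0.989 for a 99 atom% substrate). The
0.036 g ml⁻¹ full-label shift is the standard ¹³C SIP calibration. A
partially labelled population (labelled fraction w) is a two-component
Gaussian mixture: an unlabelled band at BD(GC, 0) with weight 1−w and a
labelled band at BD(GC, E) with weight w.

Band width models diffusion broadening only: σ(L) = σ₀·√(L₀/L) with
σ₀ = 0.005 g ml⁻¹ at L₀ = 10 kb. This is a deliberate one-parameter
simplification of the full Mason–Meselson treatment; only the relative
peak width across contig lengths matters to classification.

The fraction layout is linear in fraction index through two anchors,
F6 = 1.749 and F13 = 1.717 g ml⁻¹, over 35 fractions numbered heavy →
light, with F6–F13 forming the sequenced window. A contig's expected
profile integrates its BD mixture over each fraction's BD interval;
mass beyond the gradient ends accumulates in the terminal fractions
(mimicking pellet/meniscus pooling) so every profile sums to exactly 1.
The *null profile* is the same integral at E = 0 — what the contig would
show at natural abundance, controlling for GC.

A consequence worth noting: the sequenced window spans only
~0.037 g ml⁻¹, about one full-label shift. Unlabelled DNA is visible in
the window only when GC-rich (GC ≳ 0.62), which reproduces the familiar
SIP confound of unlabelled high-GC genomes in heavy fractions — the
phenomenon the null profiles exist to control.

## Synthetic communities

The generator emulates the data the analysis consumes without any
sequencing: taxa with 7-rank lineages (a bundled list of 30 soil
orders), log-normal contig lengths truncated at the 2,500 bp assembly
cutoff, per-contig GC around the taxon mean, and depth tables in the
`jgi_summarize_bam_contig_depths` column layout. Observed depths are
negative-binomial draws around μ_cf = depth × abundance × p_cf, with the
quadratic-overdispersion convention var = μ + α·μ² (the DESeq2/edgeR
"dispersion" α; default α = 0.5, i.e. strongly overdispersed — the norm
for metagenomic coverage).

Ground-truth classes follow a deterministic rule applied to the label
state: *undetermined* when expected mean window coverage < 3×; else
*bimodal* when 0.2 ≤ w ≤ 0.6 at excess ≥ 0.5; else *strong* when
w ≥ 0.8 at excess ≥ 0.5; else *weak* when the mean BD shift w·E·0.036
falls in [0.005, 0.02] g ml⁻¹ and *unenriched* below it. A residual
large-shift state (high excess at intermediate w just above the bimodal
band) is read as strong: a large mean shift without a split population
is strong enrichment. All thresholds are config-exposed.

Class-conditional parameter ranges were fixed on physical grounds —
each class's band(s) must place callable mass inside the sequenced
window: strong contigs are mid-GC and mostly labelled at high excess
(GC ≈ 0.40–0.58, E ∈ [0.65, 0.85], w ∈ [0.85, 1]); weak contigs are
fully labelled at low excess (E ∈ [0.16, 0.44]) and GC-rich enough to
band in-window; unenriched contigs are unlabelled and GC-rich
(GC ≈ 0.62–0.74); bimodal contigs are mixed populations
(w ∈ [0.25, 0.55], E ∈ [0.70, 0.85]) with both peaks near the window;
undetermined contigs are rare taxa whose coverage falls below the 3×
floor. A rejection loop re-draws parameters until the truth rule
confirms the intended class, so labels are exact by construction.

What the generator does *not* emulate: read-level errors, assembly
chimerism, strain microdiversity, inter-fraction library-size
variation, and taxon-correlated GC structure beyond the class means.
Benchmark results therefore demonstrate that the classifier recovers
enrichment structure under realistic count noise and GC confounding —
not that it would reach the same figures on any real soil metagenome.

## Profile features and the enrichment forest

Each contig yields 24 features: observed relative depth in the 8 window
fractions; null relative depth in the same 8 (the null restricted to
the window and renormalized, since observed depths exist only there);
counts of local maxima/minima and global argmax/argmin positions of the
observed profile; the null's maxima count and argmax; the
depth-weighted mean-fraction shift (observed − null; negative = mass
moved heavier); and log10(1 + total depth). Extremum positions beyond
the global argmax/argmin enter only through the counts, keeping the
vector fixed-length. Plateaus collapse to their leftmost index;
endpoints are extrema when they strictly beat their single neighbour.
No smoothing is applied before extrema detection by default (a
moving-average width is config-exposed).

The classifier is a 500-tree random forest (majority vote, √p features
per split, unlimited depth) over the five categories, trained on 600
labelled profiles with a stratified 80/20 split. Ties in the predicted
class probabilities break in the fixed order strong > weak > unenriched
> bimodal > undetermined; zero-depth contigs short-circuit to
undetermined. Tree construction and the split are seeded, so a seed
fixes the entire benchmark.

On the default benchmark, holdout metrics averaged over seeds 1–10:
overall accuracy 96.2 %, strong sensitivity 98.3 %, strong specificity
99.2 %, unenriched specificity 98.3 % (recomputed by
`tests/test_acceptance.py` and `scripts/acceptance.py`). The residual
errors are concentrated in weak-vs-unenriched and weak-vs-bimodal
confusions, which share band positions at the light edge of the window.

## Phylobins

A phylobin is the set of contigs sharing an enrichment status (strong,
weak, unenriched) and an order-rank taxon; bimodal and undetermined
contigs enter no phylobin and are reported in a side table. Lineages
missing the order rank fall back to "unclassified_" + the lowest
resolved rank; contigs with a call but no taxonomy go to
"unclassified_root". Quality filters are strict inequalities: total
length > 1 Mb and, when a completeness estimate is supplied,
completeness > 75 % (completeness estimation itself is external — when
absent the size filter alone applies). Categories combine status with
cellulolytic potential: a phylobin is cellulolytic iff any member
contig carries a family from the endoglucanase set (the 40 listed GH5
subfamilies, GH6/7/8/9/12/44/45/48/51/74/124/131, AA10 and AA9 with
GH61 as its alias). Bare "GH5" without a subfamily does not qualify;
chitinases GH18/GH19 never do.

## Traits and statistics

Trait abundances are size-normalized as rcpm = count × 10⁶ / unit size
in bp (counts per megabase). This denominator reproduces the ~1–2 rcpm
magnitudes expected for secondary-metabolite clusters on 10–25 Mb bins;
a per-million-mapped-reads denominator is supported by passing the
mapped-read total as the size. Bray-Curtis dissimilarity
d(x,y) = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ) feeds downstream ordination (the ordination
itself is out of scope). Group comparisons are rank-based: the
two-group rank-sum test (statistic W = sum of the first group's ranks)
and Kruskal-Wallis H, with exact permutation p-values when total
n ≤ 10 (full enumeration of distinct label arrangements) and the usual
large-sample approximations otherwise; two-sided throughout.

## Auxotrophy by flux balance analysis

FBA is the standard steady-state LP — maximize biomass flux subject to
S·v = 0 and bounds — solved with HiGHS. Two media are defined per
model: *rich* (every biomass precursor importable) and *minimal*
(carbon source plus the genome's essential nutrients). A reaction is
essential under a medium if knocking it out drops the optimum below 1 %
of wild type; it is coupled to a compound if, with the biomass reaction
disabled and a demand flux ≥ 0.1 imposed on the compound, its feasible
flux interval excludes zero beyond 10⁻⁶ (two LPs). A reaction is
*critical* for a compound iff it is not flagged central-carbon, is
essential under minimal but not under rich, and is coupled to the
compound. The call is: auxotrophic iff n_critical < θ or
n_gapfilled_critical > γ (defaults θ = 1, γ = 0; compound-specific
mappings accepted — for real reconstructions these must be calibrated
and supplied). "Central carbon" is an input flag on reactions, not
inferred.

Toy models give each of up to 32 target compounds (20 amino acids plus
cofactors/vitamins/nucleotide precursors) a two-step pathway from a
central precursor that is complete, gap-filled, or deleted. Deleted
compounds are supplied in the minimal medium — they are that genome's
essential nutrients; without this the model could not grow on minimal
at all and every compound would trivially appear auxotrophic. Under the
default thresholds the three statuses map to prototroph / auxotroph
(gap-fill rule) / auxotroph (missing pathway), and the calls recover
the generator's truth exactly.

## Numerical choices and limitations

- Profile conservation holds to 1e−12; boundary-straddling bands split
  mass symmetrically between adjacent fractions.
- Forest hyperparameters are common defaults, config-exposed; no
  hyperparameter search is performed.
- The benchmark (600 examples, 10 seeds) runs in well under a minute on
  one CPU; toy FBA suites (≤ ~80 reactions) in seconds.
- The exact-permutation paths are enumerative and intended for n ≤ 10;
  beyond that the approximations take over by design.
- Eukaryote metabolic models, read-level simulation, MAG binning by
  kmer/coverage covariance, and ordination fitting are out of scope.
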