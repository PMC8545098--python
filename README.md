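# sipgrade

Gradient-resolved DNA stable-isotope probing (SIP) analysis for
metagenomes: classify each assembled contig's degree of ¹³C enrichment
from its read-depth profile across CsCl gradient fractions, aggregate
enriched contigs into **phylobins** (enrichment status × taxonomic
order), and compare ecogenomic traits between them — cellulolytic
potential from CAZy endoglucanase families, size-normalized (rcpm)
trait tables with Bray-Curtis dissimilarity and rank tests, and
FBA-based auxotrophy calls on genome-scale metabolic models.

The package is aimed at microbial ecologists running DNA-SIP
experiments (e.g. ¹³C-cellulose amendments in soil) who sequence
several gradient fractions and need per-contig enrichment calls that
are robust to the classic SIP confound: unlabelled high-GC DNA banding
in heavy fractions.

## The model in brief

DNA bands at buoyant density BD = 1.660 + 0.098·GC + 0.036·E g ml⁻¹,
where E is the ¹³C atom-fraction excess; a partially labelled
population (labelled fraction w) is a two-band Gaussian mixture with
σ(L) = σ₀√(L₀/L) diffusion broadening. Integrating that mixture over
the fraction intervals of a 35-fraction gradient (anchored at
F6 = 1.749, F13 = 1.717 g ml⁻¹; F6–F13 sequenced) gives a contig's
expected gradient profile; the same integral at E = 0 is its
GC-matched **null profile**. Each contig's observed-vs-null profile
pair is summarized into 24 features (relative depths, local extrema
counts and positions, mean-fraction shift, total depth) and classified
by a 500-tree random forest into one of five categories: *strong*,
*weak*, *unenriched*, *bimodal* (maxima in both heavy and light
portions of the gradient) or *undetermined*.

A synthetic-community module generates contigs, jgi-layout depth
tables (negative-binomial noise, var = μ + α·μ²), annotation tables and
toy metabolic models with known truth, so the full pipeline runs and
validates without any sequencing data.

## Worked example

Train and validate the enrichment classifier on the default synthetic
benchmark (600 labelled contig profiles, 50× mean depth, dispersion
0.5, stratified 80/20 split):

```python
from sipgrade.benchmark import run_single
from sipgrade.synthetic import BenchmarkConfig

rep = run_single(BenchmarkConfig(), seed=1)
print(f"holdout accuracy: {rep.accuracy:.3f}")
print(f"strong: sens {rep.sensitivity['strong']:.3f}, spec {rep.specificity['strong']:.3f}")
print(rep.confusion)
```

prints

```
holdout accuracy: 0.933
strong: sens 0.944, spec 1.000
              strong  weak  unenriched  bimodal  undetermined
strong            34     0           0        2             0
weak               0    10           0        2             0
unenriched        0     1          41        0             0
bimodal           0     3           0       15             0
undetermined      0     0           0        0            12
```

i.e. on this 120-contig holdout, 93.3 % of contigs get the correct
enrichment call; 34 of 36 truly strongly-enriched contigs are
recovered (sensitivity 0.944) with no false strong calls (specificity
1.0), and the few errors sit between classes whose bands overlap at
the light edge of the sequenced window (weak/bimodal/unenriched).

The same pipeline is available from the shell:

```bash
sipgrade simulate --seed 3 -o sim/
sipgrade features --depths sim/depths.tsv --contigs sim/contigs.fasta \
         --layout sim/layout.yaml -o features.tsv
sipgrade train    --features features.tsv --labels sim/truth.tsv --seed 3 -o model.bin
sipgrade classify --features features.tsv --model model.bin -o calls.tsv
sipgrade phylobin --calls calls.tsv --taxonomy sim/taxonomy.tsv \
         --truth sim/truth.tsv --annotations sim/annotations.tsv -o bins/
```

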