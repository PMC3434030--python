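# strainarray

Probe-level microarray analysis of brain-transcriptome variation among
zebrafish (*Danio rerio*) strains with different domestication histories,
together with the behavioral and qRT-PCR arms of such a study.

Domesticated zebrafish strains (e.g. Scientific Hatcheries, TM1; ≥ ~30
generations in captivity) spend more time near the water surface and the
front of the aquarium than wild-derived strains (Nadia, Gaighatta; 1–6
captive generations). This package implements the full statistical path
from raw oligonucleotide-array probe intensities and raw tank
observations to lists of strain-, domestication- and sex-associated
genes, so that every step can be exercised and validated on synthetic
data with planted ground truth.

## What it computes

**Preprocessing (RMA).** Per-sample background correction under the
exponential-signal + normal-background convolution model
(`o = s + b`, `s ~ Exp(α)`, `b ~ N(μ, σ²)`, replacing `o` by the
closed-form `E[s | o]`), quantile normalization, and median-polish
summarization of log2 probe intensities to probe-set expression.
Present/marginal/absent detection calls come from a one-sided Wilcoxon
signed-rank test of the discrimination scores
`R_j = (PM_j − MM_j)/(PM_j + MM_j)` against τ = 0.015 (exact null for
small probe sets). Unexpressed probe sets are removed below the
99th-percentile expression of always-absent features, and low-variability
probe sets with log2 IQR < 0.5 are excluded.

**Single-feature polymorphisms (SFPs).** Sequence variants under a probe
shift that probe's affinity in carrier strains without changing
expression. The probe-set expression estimate is subtracted from each
normalized log2 probe value and the residuals are screened for a strain
effect with a SAM-style multiclass statistic
`d = sqrt(Σ_k n_k (x̄_k − x̄)²) / (s + s₀)` whose null is built from
label permutations; probe sets with any probe at q < 0.01 are removed
before differential expression.

**Differential expression.** Per-gene least squares on log2 expression
with empirical-Bayes variance moderation: residual variances `s²_g` (d
df) are shrunk toward a prior `(d₀, s₀²)` estimated by moment-matching
`log s²`, giving posterior `s̃²_g = (d₀ s₀² + d s²_g)/(d₀ + d)` and
moderated t/F statistics on `d₀ + d` df. Contrasts: among-strain omnibus
F, wild-vs-domesticated `½(μ_SH + μ_TM1) − ½(μ_Nadia + μ_Gaighatta)`,
and the sex main effect from the strain × sex factorial. P-values are
Benjamini–Hochberg adjusted (FDR 5%); the domestication list is tightened
by a range-overlap filter (wild and domesticated expression ranges may
overlap by at most one sample) and annotated with linear-scale fold
changes.

**Enrichment.** EASE scores (one-tailed Fisher exact after removing one
list hit) of annotation categories against the expressed background.

**Behavior & qPCR.** Vertical Depth (mean zone 1–6) and Horizontal
Position (proportion of recordings near the front) per fish; nested
fixed-effects ANOVA `Sex + Domestication + Strain(Domestication)` with
partial sums of squares; qRT-PCR ANCOVA of target C_T with the
reference-gene C_T as covariate, followed by Tukey studentized-range
pairwise comparisons with compact-letter grouping.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (1000 probe sets × 16 arrays, 64 fish, 16 qPCR pools) and write
their tables under `results/`:

```bash
python analysis/01_simulate.py
python analysis/02_preprocess.py
python analysis/03_sfp_screen.py
python analysis/04_differential_expression.py
python analysis/05_enrichment.py
python analysis/06_behavior_qpcr.py
```

Output of one full run:

```
planted: 450 unexpressed, 200 strain-DE, 50 domestication-DE, 10 sex-DE, 50 SFP probe sets
absent-expression threshold T = 3.798 (99th percentile)
622 probe sets above T; 260 after the IQR >= 0.5 filter
260 probe sets screened; 30 flagged at q < 0.01
planted SFP probe sets reaching the screen: 20; detected 20 (sensitivity 1.00)
among strains: 221 significant at BH 5% (180 with >= 2-fold pairwise difference)
wild vs domesticated: 119 initial -> 105 after range-overlap filter (79 >= 2-fold)
sex: 10 significant
vertical_depth: Domestication F = 350.23 (df 1, 59), p = 1.72e-26
qPCR strain F = 49.63, p = 4.39e-05
Tukey letters: Gaighatta:b Nadia:c SH:a TM1:b
```

Reading this: of 1000 simulated probe sets, the expression and
variability filters keep the 260 that carry planted effects (unexpressed
and flat probe sets are designed to fail them); the SFP screen catches
every planted polymorphism that survives filtering while flagging ~4% of
clean probe sets; the moderated models recover the planted strain and
domestication effects; and the behavior/qPCR arms reproduce the
wild-vs-domesticated separation (wild strains deeper and less
front-oriented; strains sharing a Tukey letter do not differ at α=0.05).

The same analysis is scriptable on real data: probe-level TSV tables
(`pm.tsv`/`mm.tsv` with row ids `probeset:index`, `samples.tsv` with the
strain → domestication map) feed `strainarray run --config pipeline.yaml`
or the stage subcommands (`simulate`, `preprocess`, `sfp`, `de`,
`enrich`, `behavior`, `qpcr`). A recipe for converting a deposited CEL
series to these tables is in `docs/methods.md`.

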