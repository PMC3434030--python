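# Methods

This note records the models, conventions and design choices behind
`strainarray`, at the level of detail a maintainer needs to change them
deliberately.

## Study design assumed throughout

Four strains — two wild-derived (Gaighatta, Nadia) and two domesticated
(SH, TM1) — each measured as two replicate pools per sex, 16 arrays in
total. The strain → domestication map is data-driven (read from
`samples.tsv`), so other strain panels analyze without code changes.
Replicate pools are treated as independent, equally weighted units
regardless of pool size (3–5 fish); no weighting information is
available to justify anything else.

## Generative model of the synthetic arrays

Probe intensities are additive on the log2 scale with an additive
optical background — the model RMA-style preprocessing assumes:

    PM_ij = 2^(μ_gs + φ_j + sfp_js + ε_ij) + B_ij
    MM_ij = 2^(φ_j + ε'_ij)                + B'_ij

with per-probe-set expression μ_gs (baseline ~ N(8, 1) log2 plus planted
effects), probe affinity φ_j ~ N(0, 1), measurement noise ε ~ N(0,
0.25), and background B ~ N(100, 10) truncated positive. MM carries no
true-signal term (cross-hybridization only), which is what makes the
PM−MM discrimination score informative for detection calls. Unexpressed
probe sets (45% by default, matching roughly half the array being silent
in a single tissue) have no signal term at all.

Planted effects: 20% of probe sets vary among strains (a random 2/2
strain split at ±effect/2 — a two-group pattern keeps the probe-set IQR
comparable to the effect size, as single-strain outlier patterns would
be mostly invisible to an IQR filter at realistic effect sizes), 5%
differ by domestication, 1% by sex. Effect magnitudes are N(1.2, 0.4)
log2 floored at 0.8, so planted fold changes span roughly 1.85×–5.6× —
the range the downstream 2-fold summaries are designed to resolve.

SFPs are planted on 5% of probe sets (expressed ones only: a probe-level
shift on a silent probe set is invisible against background), two probes
per affected set, as a −1.5 log2 affinity shift shared by all samples of
the carrier strain(s). This is the standard genetic interpretation of
probe-level polymorphism: constant within strain, absent from the
probe-set mean after robust summarization.

What the generator does **not** emulate: spatial array artifacts, batch
effects, RNA degradation, probe GC effects, correlated biological
variability among non-DE genes. Consequently, passing tests demonstrate
the statistical machinery is correct under its own assumptions, not that
the pipeline is robust to all failure modes of real arrays. One visible
consequence: non-DE expressed probe sets carry only measurement noise,
so the IQR filter removes nearly all of them — including SFP carriers
without an expression effect. That is faithful behavior (the filter
precedes the SFP screen), and end-to-end SFP recovery is therefore
scored on the probe sets that reach the screen.

## Preprocessing conventions

**Background correction.** Per sample, (μ, σ, α) are estimated
mode-based: μ is the mode of a Gaussian-KDE of the intensities, σ the
RMS spread of sub-mode intensities (left half of the background normal),
α the reciprocal mean excess above the mode. Corrected values are the
closed-form posterior mean of the exponential+normal convolution,
with the signal constrained to [0, o]:

    a = o − μ − σ²α
    E[s|o] = a + σ·(φ(a/σ) − φ((o−a)/σ)) / (Φ(a/σ) + Φ((o−a)/σ) − 1)

This is strictly positive and monotone in `o` within a sample (verified
against numerical quadrature to 1e-6). A constant-intensity sample is a
hard error: the density mode is undefined.

**Quantile normalization.** Value at rank r = mean over samples of each
sample's r-th order statistic. Within-column ties receive the mean of
their would-be rank values. Note these two requirements interact: for
tie-free data all per-sample sorted vectors are *exactly* equal
afterwards; with ties, the tie-averaging convention perturbs a column's
sorted vector wherever tie patterns differ between columns. Both
behaviors are intentional and tested separately.

**Median polish.** Row (probe) sweep before column (sample) sweep,
tolerance 0.01 on the change in total absolute residual, at most 10
iterations. Expression = overall + sample effect; probe effects absorb
affinities. Verified cell-exact against an independent loop-based
implementation, including robustness to gross single-cell outliers.

**Detection calls.** R_j = (PM_j − MM_j)/(PM_j + MM_j), one-sided
signed-rank test of H0: median(R) = τ against "greater", τ = 0.015.
Exact null by enumeration of all 2^n sign assignments for n ≤ 12 probes
(valid under ties, and necessary: 11 identical positive scores have
exact p = 1/2048, which a normal approximation misses); tie-corrected
normal approximation with continuity correction otherwise. Call = P iff
p < 0.04, A iff p > 0.04, else M; marginal counts as absent everywhere
downstream.

**Expression filter.** T = the 0.99 quantile (linear interpolation) of
expression values of probe sets absent (A or M) in *every* sample,
pooled over samples by default (`pooled=False` gives the max of
per-sample quantiles — the alternative reading of "across all samples").
A probe set is removed when its max expression over samples is < T.
Re-applying the filter recomputes T from a shrunken absent pool, so
idempotence holds when the derived T is passed back explicitly
(`threshold=` argument); the pipeline computes T once.

**IQR filter.** Linear-interpolation quantiles; removal is strict
(`IQR < 0.5` removed, exactly 0.5 retained). Both quantile conventions
are configurable because they change counts at boundaries.

## SFP screen

Residual r_{ji} = normalized log2 probe value − probe-set expression.
Multiclass statistic per probe: d = sqrt(Σ_k n_k (x̄_k − x̄)²)/(s + s₀),
s = pooled within-strain SD, s₀ = 5th percentile of the s distribution
("auto"; a grid-searched s₀ is unnecessary because significance is
permutation-calibrated, and any strictly monotone rescaling of d leaves
the q-value ranking unchanged). The null is built from seeded label
permutations (1000 by default); q(probe) = median over permutations of
#{permuted d ≥ d_j} divided by #{observed d ≥ d_j}, clipped to [0, 1]
and made monotone non-increasing in d by a reverse cumulative minimum.
Permutations use the 4 strain labels (not the 2-level domestication
factor). A probe set is flagged when ≥ 1 member probe has q < 0.01
(`min_probes` raises the bar). Null calibration: on pure-noise
residuals the flagged fraction at q < 0.01 is ≪ 0.02.

## Differential expression

Cell-means designs (one indicator per strain; the factorial adds a male
main effect and strain × male interactions). OLS per probe set; the
moderation prior (d₀, s₀²) comes from matching the mean and variance of
log s² to the scaled-F model via digamma/trigamma (Newton inversion of
the trigamma). Edge cases: d₀ = 0 reproduces classical t exactly
(regression-tested to 1e-10); identical s² across genes give d₀ = ∞ and
every posterior collapses to the moment-matched prior — which carries
the log-chi-square bias correction, i.e. s₀² is *not* the raw common s²
(for d = 12 the factor is ≈ 1.09).

The among-strain and domestication tests use the strain-only model; the
sex test uses the factorial model (the interaction is rarely relevant
and a sex-free model is more powerful for strain effects). The
domestication test is a contrast within the 4-strain model, not a
re-fit 2-group model, so strain-level variance stays in the residual
where it belongs; positive = higher in domesticated. "≥ 2-fold" is
inclusive; for the among-strain list it means the max over the 6
pairwise strain comparisons. Range-overlap: a sample equal to the other
group's extreme counts as inside; a candidate survives with ≤ 1
overlapping sample (both conventions change printed counts and are
documented for that reason).

Quality-control probe sets (`AFFX-` prefix, e.g. GFP/CFP features of a
transgenic strain) ride through preprocessing but are excluded before
the SFP screen, so every ledger count is control-free by construction;
`controls_post_hoc=True` reproduces the ordering in which controls are
dropped only from the final lists.

## Enrichment

EASE score = hypergeometric upper tail after decrementing the list hits
by one (p = 1 at zero hits). The background must be the expressed set —
passing a list gene absent from the background is an error, not a
warning, because a whole-array background silently inflates
significance. BH-adjusted p-values are reported alongside. Reproducing
any specific category database (or hierarchy-aware pruning) is out of
scope; annotation is user-supplied TSV.

## Behavior and qPCR

Scores: Vertical Depth = mean over periods of the within-period mean
zone (incomplete periods contribute what they have); Horizontal
Position = overall proportion of front flags. The ANOVA uses partial
(Type-III-style, sum-to-zero coding) sums of squares because the real
design is slightly sex-imbalanced; Type I is available
(`ss_type="sequential"`). Nesting is written `strain(domestication)`.
Residual skew/kurtosis and a D'Agostino–Pearson p are reported but never
gate the analysis. The simulator's behavior arm targets repeatability
(intraclass correlation) 0.5 via equal between-fish and within-fish
latent SDs of 0.6 zone units; zone discretization and 1–6 clamping keep
the realized ICC inside 0.4–0.6.

The qPCR ANCOVA is `ct_target ~ ct_reference + Strain + Sex +
Strain:Sex`; a constant reference C_T is dropped with a warning (the
model degenerates to the two-way ANOVA). Adjusted strain means are
predictions at the mean reference C_T averaged over sexes. Tukey
comparisons use the studentized range with the Tukey–Kramer SE for
unequal n; compact letters come from maximal runs of mutually
non-different groups in mean order.

## Problem sizes and seeds

Default synthetic runs use 1000 probe sets × 11 probes × 16 samples and
1000 permutations, which keeps a full pipeline run under ~10 s and the
complete validation suite in the low minutes on one CPU; these sizes
give the permutation nulls and recovery rates comfortable resolution at
the study's sample size. All stochastic stages take explicit seeds and
runs are bit-reproducible; changing only the seed changes permutation
q-values but no deterministic stage output.

## Converting a deposited CEL series

The pipeline consumes text tables, not binary CEL files. To analyze a
GEO series, export probe-level PM/MM matrices with Bioconductor, e.g.:

```r
library(affy)
ab <- ReadAffy()                      # CEL files in the working directory
pm_m <- pm(ab); mm_m <- mm(ab)
ids  <- rep(probeNames(ab), 1)        # probeset per PM row
idx  <- ave(seq_along(ids), ids, FUN = seq_along)
rownames(pm_m) <- rownames(mm_m) <- paste(ids, idx, sep = ":")
write.table(pm_m, "pm.tsv", sep = "\t", quote = FALSE, col.names = NA)
write.table(mm_m, "mm.tsv", sep = "\t", quote = FALSE, col.names = NA)
```

plus a hand-written `samples.tsv` mapping array → strain/domestication/
sex/pool size.

## Known limitations

- Background-parameter estimation needs a visible background mode; an
  array where essentially every feature is expressed will mis-place μ.
- Quantile normalization assumes comparable intensity distributions; it
  redistributes genuine global distribution differences between samples
  into per-gene distortion (inherent to the method, visible in the
  mirrored-pair recovery test).
- The SFP screen detects polymorphisms only in probe sets that pass the
  expression/variability filters, and cannot separate a polymorphism
  shared by all 16 samples' strains equally (no strain contrast).
- Permutation q-values have resolution limited by the number of
  permutations and, for small probe counts, by the discreteness of the
  observed-count denominator.
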