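# Methods

## Generative model of a TRAP-seq study

A tissue is modelled as a mixture of cell populations `p = 1..P` with
fractions `f_p` summing to 1. Each population carries a per-gene
transcription level `x_pg` (arbitrary units per cell) and a per-gene
translation efficiency `t_pg ≥ 0`. Populations are assumed to contribute
**equal total RNA per cell**: each population's `x` vector is normalised to
unit sum before mixing (`x̂_pg`), and a per-population `rna_content`
multiplier (default 1) is exposed for sensitivity analysis. This is the
simplest assumption under which the 1/f bound below is exact.

The three sample kinds have noiseless relative-abundance profiles

- tissue transcriptome: `q_g ∝ Σ_p f_p x̂_pg`
- tissue translatome:   `q_g ∝ Σ_p f_p x̂_pg t_pg`
- cell-type IP:         `q ∝ (1−β)·norm(x̂_target t_target) + β·norm(Σ_p f_p x̂ t)`

each normalised to sum 1. The IP background fraction `β ∈ [0,1]` models
nonspecifically captured material. We take the contaminant to be the tissue
**translatome**, not the transcriptome, because the IP step purifies
ribosome-bound RNA; unbound RNA is washed away, so what is carried over
nonspecifically is polysome-bound material from other cell types. This is a
modelling choice — the alternative (total-RNA carryover) would make the
transcriptome filter look slightly better at high β — and is isolated in
one line of `expected_profile`.

**The 1/f bound.** With uniform translation efficiency and equal RNA per
cell, a transcript exclusive to a target population at fraction `f` has IP
abundance `x̂_g` and tissue-translatome abundance `f·x̂_g`, so its fold
change is exactly `1/f`; any shared expression only lowers it.
`max_theoretical_fc(f) = 1/f` is the supremum, and the property suite
verifies it over random mixtures. The canonical settings are `f = 0.02`
(rare, endothelial-like; bound 50) and `f = 0.5` (abundant,
dorsal-telencephalon-lineage-like; bound 2). The abundant fraction is not a
measured quantity; 0.5 is used as the canonical value consistent with a
maximum fold change of about two.

**Catalogs.** Genes are coding / short noncoding / long noncoding in
fractions (0.8, 0.1, 0.1) by default, apportioned by largest-remainder
rounding. Transcript lengths are log-normal per biotype: coding around
2 kb (σ_ln 0.7), short noncoding around 100 nt (σ_ln 0.5, the miRNA/snoRNA
size range), long noncoding around 1.5 kb (σ_ln 0.8). Lengths only enter
RPKM and the length/enrichment regression.

**Translation efficiencies.** Drawn once per gene and shared across
populations: `ln t = slope·(log10 L − mean log10 L) + ε`,
`ε ~ N(0, te_sd)`, then forced to 0 for short noncoding genes (they are not
ribosome-bound, which is what makes TRAP deplete them). `te_sd = 0`,
`slope = 0` gives uniform translation — the regime in which the
transcriptome and translatome references coincide for coding genes.
`te_sd = 0.5` gives realistic translational regulation in which ~8% of
genes are more than 2-fold better translated than the median — exactly the
genes the transcriptome filter miscalls for abundant populations.
`slope = −0.5` reproduces a weak shorter-is-better-translated trend.

**Markers.** Each population receives `n_marker_genes` disjoint coding
genes whose transcription is `marker_effect`-fold the shared baseline in
that population only. Baseline transcription is log-normal with σ_ln = 1.2,
a typical bulk expression spread; markers are the ground-truth enriched
set.

**Counts.** Sample `j` with library size `N_j` gets independent per-gene
counts with mean `μ = N_j q_g` and variance `μ + αμ²` (gamma-Poisson;
`α = 0` is Poisson). One master seed spawns a child stream per sample in
sample-sheet order, so appending samples never perturbs earlier ones.

## Quantification

Size factors are median-of-ratios: over genes with strictly positive
counts in every sample, `s_j = median_g k_gj / geomean(k_g·)`, midpoint
median for even counts, no rescaling. RPKM uses
`k·10⁹ / (length_nt · D_j)` with `D_j` the sample's total catalog-assigned
reads — the only depth observable in a count-level artifact. Condition
means are plain arithmetic means over replicates.

## Differential expression

`NBExactTest` implements the classical count-based two-group recipe:

- **Dispersion**: per-gene method of moments
  `α_raw = max(0, (w − m)/m²)` with `m` the pooled mean and `w` the pooled
  (Bessel-corrected) within-group variance of normalised counts; a
  least-squares fit of `α_raw` on `1/m` supplies the mean-dispersion trend,
  and the final `α̂ = max(α_raw, trend(m), 10⁻⁸)` — conservative "take the
  larger" sharing. The trend is fitted only on genes with `m ≥ 1`: below
  one normalised count, `1/m` explodes and `α_raw` is pure noise, and
  letting those genes into the fit can tilt the line arbitrarily.
- **Exact test**: conditioned on the total `K_S = K_A + K_B` of raw group
  sums. Under the null the group sum has mean `q̂·S` (with `S` the group's
  summed size factors, `q̂ = K_S/(S_A+S_B)`) and variance
  `q̂·S + α̂·q̂²·Σ_j s_j²` — per-library NB noise accumulated over the
  group; the sum is treated as NB with those two moments (Poisson when
  variance ≤ mean). The two-sided p-value sums the probabilities of all
  splits no more likely than the observed one, divided by the total. Ties
  are included at relative tolerance 1e-8. For `K_S > 10 000` the
  enumeration is windowed to ±20 null SD around the mean (always including
  the observed split) and renormalised; the truncated mass is far below
  any decision threshold.
- **Fold change**: B over A on normalised means, `+inf` when A = 0 < B,
  defined as 1 when both means are zero (no evidence either way). BH
  adjustment is per comparison.

On a null simulation (shared profile, α = 0.1, 2000 genes, 3 vs 3,
depth 10⁶) the empirical type-I error at nominal 0.05 is ≈ 0.035–0.04 —
slightly conservative, as expected from the max-sharing dispersion and the
discreteness of the exact test.

## Filter evaluation

Enrichment calls require `FC > fc_min` (default 2), `padj < padj_max`
(default 0.001) and reference-condition mean RPKM above `rpkm_floor`
(default 1); infinite FC passes any threshold. The RPKM floor uses the
reference named by the call (transcriptome floor for the transcriptome
filter, translatome floor for the translatome filter). Threshold ties are
strict (`>`) for enrichment calls but inclusive (`≥`) for the
organ-marker rules (defaults: ≥ 4-fold between organs, ≥ 2-fold versus the
within-organ reference, ≥ 5 RPKM), following the "greater than" versus "at
least" phrasing of each rule.

The dual-filter comparison reports the Venn partition and Jaccard overlap
of the two call sets, the cross-classification of transcriptome-called
genes by their translatome-comparison status (enriched / not significant /
depleted — a strict partition), a fold-change threshold sweep (default 40
log-spaced thresholds from 1 to 32, spanning the 2× and 4× operating
points), confusion-matrix metrics against the simulated truth
(truth labels: noiseless β = 0 fold change strictly above the call
threshold, against each filter's own reference), expression-stratified DE
fractions, biotype fold-change histograms (infinite values assigned to the
outermost bins), and an ordinary least-squares regression of log2 FC on
log10 length via `scipy.stats.linregress`.

## Canonical study conditions and problem sizes

- Rare population: f = 0.02, 5000 genes, 300 planted 8-fold markers,
  β = 0.05, depth 2×10⁶, 3 replicates per condition, α = 0.05, no
  translational regulation. Expected outcome: both filters ≥ 0.95
  sensitivity, ≈ 0 FDR, Jaccard ≥ 0.95.
- Abundant population: same generator at f = 0.5 with te_sd = 0.5.
  Expected outcome: the translatome filter calls almost nothing (the 2-fold
  ceiling), the transcriptome filter calls hundreds of well-translated
  genes, and essentially all of its exclusive calls are unconfirmed or
  depleted versus the translatome.
- Null calibration: 2000 genes, α = 0.1, 3 vs 3 at depth 10⁶.
- Noncoding depletion: 3000 genes with 20% short noncoding, depth 2×10⁶;
  among short noncoding genes with expected transcriptome count ≥ 100,
  the fraction with negative translatome log2 FC is reported (≈ 1.0, since
  their translatome abundance is exactly zero).
- Length trend: 2000 genes, slope −0.5, te_sd = 0.5; the recovered
  regression slope is negative with a weak-to-moderate r, i.e. length is a
  real but weak predictor.

The dispersion α = 0.05 used outside the calibration run is a typical
bulk-RNA-seq biological-replicate value; σ_ln = 1.2 for transcription and
the per-biotype length laws are likewise chosen once as field-typical.
These sizes keep the full test suite and the acceptance script to a few
minutes on one CPU while leaving every qualitative contrast far from its
decision boundary.

## What the simulation does and does not show

The generator reproduces the structural features that drive the filtering
question — mixture composition, translational regulation, background
contamination, NB counting noise, biotype-specific translation — but not
real-data complications: mappability and annotation error, GC/length
sequencing bias beyond the RPKM length term, correlated replicates, isoform
mixtures, or cell-type-specific translation efficiencies (t is shared
across populations, so translatome-reference false positives from
*differential* translational regulation between cell types are not
modelled). Passing tests therefore validate the logic and calibration of
the pipeline and the abundance argument, not the exact operating
characteristics on any particular real dataset.

## Numerical choices

- Expected profiles validated to sum to 1 within 1e-12; all-zero profiles
  (e.g. a translatome when every t = 0) raise instead of silently dividing.
- Exact-test tie tolerance 1e-8 relative; p clipped to [0,1].
- Dispersion floor 10⁻⁸; all-zero genes flagged and floored.
- Largest-remainder rounding for biotype apportionment (stable argsort for
  reproducible tie-breaks).
- Truth fold changes use a +inf sentinel for target-exclusive genes and 0
  for target-absent genes; both compare correctly against any finite
  threshold.
- Seeds: every public entry point takes one integer seed;
  `numpy.random.SeedSequence` spawning derives per-sample and per-stage
  streams.
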