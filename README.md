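# trapfe

Simulation and evaluation of filtering strategies for TRAP-seq translatome
profiling.

## The problem

Translating-ribosome affinity purification (TRAP) recovers the
ribosome-bound RNA of a genetically labelled cell population directly from
intact tissue. The immunoprecipitated (IP) sample is always contaminated by
background RNA from the surrounding tissue, so cell-type-enriched
transcripts must be called by fold change against a whole-tissue reference.
Two references are possible:

- the tissue **transcriptome** (total RNA) — needs only the cell-type Cre
  driver, but assumes transcription and translation track each other;
- the tissue **translatome** (pan-cellular TRAP) — the like-for-like
  reference, but needs a second, ubiquitous Cre driver.

Whether the cheap transcriptome filter is good enough turns out to depend on
the abundance of the profiled population. For a transcript expressed
exclusively in a population making up a fraction *f* of the tissue's cells,
the IP-versus-tissue fold change is bounded by

&nbsp;&nbsp;&nbsp;&nbsp;FC<sub>max</sub> = 1 / *f*

(under equal total RNA per cell and uniform translation efficiency). A rare
population such as endothelial cells (*f* ≈ 0.02) admits 50-fold enrichment,
so genuine markers tower over translational-regulation noise; an abundant
lineage at *f* = 0.5 admits at most 2-fold enrichment, the same order as
ordinary transcriptome/translatome differences, and the transcriptome filter
breaks down.

`trapfe` makes this argument quantitative and testable: it simulates a
tissue as a mixture of cell populations with known transcription levels,
translation efficiencies and ground-truth markers, generates
negative-binomial sequencing libraries for the three sample kinds
(transcriptome, translatome, cell-type IP with background fraction β), runs
a count-based differential-expression analysis, and scores both filters
against the simulated truth.

## What is inside

- `trapfe.mixture` / `trapfe.catalog` / `trapfe.simulate` — the generative
  model: gene catalogs (coding / short noncoding / long noncoding, with
  transcript lengths), population mixtures, exact expected profiles, the
  `max_theoretical_fc(f) = 1/f` bound, ground-truth enrichment labels, and
  seeded NB count sampling (variance μ + αμ²).
- `trapfe.de` — a statsmodels-style model/results pair (`NBExactTest` →
  `NBExactTestResults`): median-of-ratios size factors, method-of-moments
  dispersion with a 1/mean trend shared conservatively, the conditioned NB
  exact test on group sums, Benjamini–Hochberg adjustment, and fold changes
  with an `inf` sentinel for exclusive expression.
- `trapfe.evaluate` — enrichment calling (FC > 2, padj < 0.001, > 1 RPKM by
  default), Venn comparison of the two filters, cross-classification of
  transcriptome-only calls against the translatome comparison, fold-change
  threshold sweeps, organ-specific marker derivation, expression-stratified
  DE fractions, fold-change histograms by biotype, and the
  length-versus-enrichment regression.
- `trapfe.benchmarks` — ready-made studies (rare population, abundant
  population, null calibration, noncoding depletion, length trend, the 1/f
  bound suite).
- `trapfe.pipeline` / `trapfe.cli` — TSV/JSON/YAML formats and the
  `trapfe simulate|quantify|detest|evaluate|run|fixtures` command line.

## Worked example

```python
from trapfe.benchmarks import filter_comparison_study

# rare population: f = 0.02, 60 planted 8-fold markers among 1000 genes
rare = filter_comparison_study(7, n_genes=1000, n_markers=60, depth=400_000)
print(rare.summary())

# abundant population: f = 0.5, translational regulation on
abundant = filter_comparison_study(7, n_genes=1000, n_markers=60,
                                   depth=400_000, f_target=0.5, te_sd=0.5)
print(abundant.summary())
```

prints

```
Dual-filter comparison (f = 0.02, max theoretical FC = 50)
  transcriptome filter: 58 calls, sensitivity 0.967, FDR 0.000
  translatome filter:   58 calls, sensitivity 0.967, FDR 0.000
  Venn (only-translatome / both / only-transcriptome): 0 / 58 / 0
  Jaccard overlap: 1.000
  transcriptome-only calls not confirmed vs translatome: 0.000

Dual-filter comparison (f = 0.5, max theoretical FC = 2)
  transcriptome filter: 55 calls, sensitivity 0.702, FDR 0.273
  translatome filter:   4 calls, sensitivity nan, FDR 1.000
  Venn (only-translatome / both / only-transcriptome): 2 / 2 / 53
  Jaccard overlap: 0.035
  transcriptome-only calls not confirmed vs translatome: 1.000
```

For the rare population the two filters recover the same marker set
(Jaccard 1.0) with high sensitivity and no false discoveries — filtering
with the cheaper transcriptome reference is safe. For the abundant
population almost no transcript can clear the 2-fold ceiling in the
like-for-like translatome comparison (4 calls, none of them true markers),
while the transcriptome filter confidently calls 55 genes — nearly all of
which are merely well-translated, not cell-type-specific: 100% of its
exclusive calls are unconfirmed or depleted in the translatome comparison.
That is precisely why abundant lineages require the translatome reference.

The same analysis runs end to end from a config file:

```sh
trapfe run --config examples/rare_population.yaml --out-dir out/
```

writing the catalog, sample sheet, counts, truth table, RPKM, size factors,
three DE tables, call lists, the threshold sweep and `report.json`.

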