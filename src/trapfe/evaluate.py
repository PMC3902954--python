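"""Enrichment calling and dual-filter evaluation.

A cell-type IP translatome can be filtered against two whole-tissue
references — the transcriptome (one Cre driver needed) or the translatome
(two drivers needed).  This module calls enriched transcripts under either
reference, compares the two call sets (Venn overlap, cross-classification
of transcriptome-only calls against the translatome comparison, a
fold-change threshold sweep), derives organ-specific marker sets, and
scores calls against simulated ground truth.

Default thresholds: fold change > 2 with adjusted P < 0.001, restricted to
transcripts above 1 RPKM in the reference condition; organ-marker rules use
"at least" (>=) comparisons with a 4-fold between-organ and 2-fold
versus-reference requirement at a minimum of 5 RPKM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import validate_catalog

DEFAULT_FC_MIN = 2.0
DEFAULT_PADJ_MAX = 0.001
DEFAULT_RPKM_FLOOR = 1.0
DEFAULT_FC_BETWEEN = 4.0
DEFAULT_FC_REF = 2.0
DEFAULT_RPKM_MIN = 5.0
#: default threshold-sweep grid: 40 log-spaced points spanning 1..32
DEFAULT_TAU_GRID = tuple(np.logspace(0, 5, 40, base=2.0))


@dataclass
class EnrichmentCall:
    """A called gene set with the thresholds that produced it."""

    genes: list[str]
    reference: str
    fc_min: float
    padj_max: float
    rpkm_floor: float

    @property
    def gene_set(self) -> frozenset:
        return frozenset(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class CrossClassification:
    """Status of transcriptome-called genes in the translatome comparison."""

    enriched: list[str]
    not_significant: list[str]
    depleted: list[str]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "enriched": len(self.enriched),
            "not_significant": len(self.not_significant),
            "depleted": len(self.depleted),
        }

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())


@dataclass
class TruthMetrics:
    """Confusion counts and derived rates of a call set against truth."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def fdr(self) -> float:
        return self.fp / max(1, self.tp + self.fp)


def call_enriched(
    de: pd.DataFrame,
    mean_rpkm: pd.Series,
    fc_min: float = DEFAULT_FC_MIN,
    padj_max: float = DEFAULT_PADJ_MAX,
    rpkm_floor: float = DEFAULT_RPKM_FLOOR,
    reference: str = "transcriptome",
) -> EnrichmentCall:
    """Call genes enriched in the IP over one reference.

    A gene is called iff ``fold_change > fc_min`` (an infinite fold change
    passes any threshold), ``padj < padj_max`` and the reference-condition
    ``mean_rpkm > rpkm_floor``.
    """
    if min(fc_min, padj_max, rpkm_floor) < 0:
        raise ValueError("thresholds must be non-negative")
    rpkm_aligned = mean_rpkm.reindex(de.index)
    mask = (
        (de["fold_change"] > fc_min)
        & (de["padj"] < padj_max)
        & (rpkm_aligned > rpkm_floor)
    )
    return EnrichmentCall(
        genes=list(de.index[mask]),
        reference=reference,
        fc_min=fc_min,
        padj_max=padj_max,
        rpkm_floor=rpkm_floor,
    )


def venn_compare(
    call_a: EnrichmentCall, call_b: EnrichmentCall
) -> dict[str, list[str] | int]:
    """Exact partition of two call sets into only-A / both / only-B."""
    a, b = call_a.gene_set, call_b.gene_set
    only_a, both, only_b = sorted(a - b), sorted(a & b), sorted(b - a)
    return {
        "only_a": len(only_a), "both": len(both), "only_b": len(only_b),
        "only_a_genes": only_a, "both_genes": both, "only_b_genes": only_b,
    }


def jaccard(call_a: EnrichmentCall, call_b: EnrichmentCall) -> float:
    a, b = call_a.gene_set, call_b.gene_set
    union = a | b
    return len(a & b) / len(union) if union else float("nan")


def cross_classify(
    transcriptome_call: EnrichmentCall,
    de_vs_translatome: pd.DataFrame,
    padj_max: float = DEFAULT_PADJ_MAX,
) -> CrossClassification:
    """Classify transcriptome-called genes by their translatome-comparison
    status: significantly enriched, not significant, or significantly
    depleted.  The three categories partition the call set."""
    genes = transcriptome_call.genes
    missing = set(genes) - set(de_vs_translatome.index)
    if missing:
        raise ValueError(
            f"genes missing from the translatome comparison: {sorted(missing)[:5]}"
        )
    sub = de_vs_translatome.loc[genes]
    sig = sub["padj"] < padj_max
    enriched = sig & (sub["log2fc"] > 0)
    depleted = sig & (sub["log2fc"] < 0)
    return CrossClassification(
        enriched=list(sub.index[enriched]),
        not_significant=list(sub.index[~(enriched | depleted)]),
        depleted=list(sub.index[depleted]),
    )


def threshold_sweep(
    transcriptome_de: pd.DataFrame,
    translatome_de: pd.DataFrame,
    mean_rpkm: pd.Series,
    tau_grid: tuple[float, ...] = DEFAULT_TAU_GRID,
    padj_max: float = DEFAULT_PADJ_MAX,
    rpkm_floor: float = DEFAULT_RPKM_FLOOR,
) -> pd.DataFrame:
    """Apply a gradually increasing fold-change threshold to the
    transcriptome-filter calls and count how each shrinking set classifies
    against the translatome comparison.

    Returns a frame with columns ``tau``, ``confirmed_enriched``,
    ``not_significant``, ``depleted``, ``total``.
    """
    taus = list(tau_grid)
    if not taus:
        raise ValueError("tau_grid must not be empty")
    if any(b <= a for a, b in zip(taus, taus[1:])):
        raise ValueError("tau_grid must be strictly increasing")
    rows = []
    for tau in taus:
        call = call_enriched(
            transcriptome_de, mean_rpkm, fc_min=tau, padj_max=padj_max,
            rpkm_floor=rpkm_floor, reference="transcriptome",
        )
        cc = cross_classify(call, translatome_de, padj_max=padj_max)
        rows.append(
            {
                "tau": tau,
                "confirmed_enriched": len(cc.enriched),
                "not_significant": len(cc.not_significant),
                "depleted": len(cc.depleted),
                "total": cc.n_total,
            }
        )
    return pd.DataFrame(rows)


def organ_marker_sets(
    de_between: pd.DataFrame,
    de_ref: pd.DataFrame,
    mean_rpkm_target: pd.Series,
    fc_between: float = DEFAULT_FC_BETWEEN,
    fc_ref: float = DEFAULT_FC_REF,
    rpkm_min: float = DEFAULT_RPKM_MIN,
    padj_max: float = DEFAULT_PADJ_MAX,
) -> EnrichmentCall:
    """Derive organ-specific markers for a target cell population.

    A gene qualifies iff it is at least ``fc_between``-fold higher in the
    target organ's population than the other organ's (``de_between``), at
    least ``fc_ref``-fold enriched over the within-organ reference
    (``de_ref``), expressed at a minimum of ``rpkm_min`` in the target, and
    significant (padj < padj_max) in both comparisons.
    """
    if not de_between.index.equals(de_ref.index):
        raise ValueError("the two DE tables must be aligned on the same genes")
    rpkm_aligned = mean_rpkm_target.reindex(de_between.index)
    mask = (
        (de_between["fold_change"] >= fc_between)
        & (de_ref["fold_change"] >= fc_ref)
        & (rpkm_aligned >= rpkm_min)
        & (de_between["padj"] < padj_max)
        & (de_ref["padj"] < padj_max)
    )
    return EnrichmentCall(
        genes=list(de_between.index[mask]),
        reference="organ_marker",
        fc_min=fc_between,
        padj_max=padj_max,
        rpkm_floor=rpkm_min,
    )


def truth_metrics(call: EnrichmentCall, truth_labels: pd.Series) -> TruthMetrics:
    """Score a call set against boolean ground-truth labels (indexed by
    gene over the shared gene universe)."""
    called = truth_labels.index.isin(call.gene_set)
    true = truth_labels.to_numpy(dtype=bool)
    return TruthMetrics(
        tp=int((called & true).sum()),
        fp=int((called & ~true).sum()),
        fn=int((~called & true).sum()),
        tn=int((~called & ~true).sum()),
    )


def de_fraction_by_stratum(
    de: pd.DataFrame,
    mean_rpkm: pd.Series,
    edges: tuple[float, ...] = (1.0, 5.0, 25.0),
    padj_max: float = DEFAULT_PADJ_MAX,
    lfc_bands: tuple[float, ...] = (1.0, 2.0),
) -> pd.DataFrame:
    """Fraction of genes significantly regulated, per expression stratum.

    Genes are stratified by their reference-condition mean RPKM at the
    given ``edges`` (open-ended on both sides).  For each stratum the
    fraction with ``padj < padj_max`` is reported (NaN for an empty
    stratum), further split by absolute log2 fold-change bands at
    ``lfc_bands``.
    """
    edges = list(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly increasing")
    bounds = [-np.inf] + edges + [np.inf]
    rpkm_aligned = mean_rpkm.reindex(de.index)
    sig = (de["padj"] < padj_max).to_numpy()
    abs_lfc = de["log2fc"].abs().to_numpy()
    band_bounds = [0.0] + list(lfc_bands) + [np.inf]
    rows = []
    for lo, hi in zip(bounds, bounds[1:]):
        in_stratum = ((rpkm_aligned > lo) & (rpkm_aligned <= hi)).to_numpy()
        n = int(in_stratum.sum())
        row = {
            "stratum": f"({lo:g}, {hi:g}]",
            "n_genes": n,
            "fraction_significant": float(sig[in_stratum].mean()) if n else np.nan,
        }
        for blo, bhi in zip(band_bounds, band_bounds[1:]):
            in_band = in_stratum & sig & (abs_lfc > blo) & (abs_lfc <= bhi)
            row[f"fraction_lfc_({blo:g},{bhi:g}]"] = (
                float(in_band.sum() / n) if n else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def fc_histogram(
    de: pd.DataFrame,
    catalog: pd.DataFrame,
    biotypes: tuple[str, ...] | None = None,
    bin_edges: np.ndarray | None = None,
) -> pd.DataFrame:
    """Histogram of log2 fold changes, optionally restricted to biotypes.

    Infinite fold changes are assigned to the outermost bins so the counts
    partition the (filtered) gene set.
    """
    validate_catalog(catalog)
    lfc = de["log2fc"].copy()
    if biotypes is not None:
        biotype = catalog.set_index("gene_id")["biotype"].reindex(de.index)
        lfc = lfc[biotype.isin(biotypes)]
    if bin_edges is None:
        bin_edges = np.linspace(-6.0, 6.0, 25)
    finite = lfc[np.isfinite(lfc)]
    if len(finite) and (
        (finite < bin_edges[0]).any() or (finite > bin_edges[-1]).any()
    ):
        raise ValueError("bin edges do not cover the observed finite log2fc")
    clipped = np.clip(
        lfc.to_numpy(), bin_edges[0], np.nextafter(bin_edges[-1], -np.inf)
    )
    idx = np.digitize(clipped, bin_edges) - 1
    counts = np.bincount(idx[~np.isnan(clipped)].astype(int),
                         minlength=len(bin_edges) - 1)
    return pd.DataFrame(
        {"bin_left": bin_edges[:-1], "bin_right": bin_edges[1:], "count": counts}
    )


def length_fc_regression(
    de: pd.DataFrame, catalog: pd.DataFrame
) -> tuple[float, float, float]:
    """Least-squares regression of log2 fold change on log10 transcript
    length, over genes with finite fold changes.

    Returns ``(slope, intercept, r)``; a negative slope means shorter
    transcripts are more translatome-enriched.
    """
    validate_catalog(catalog)
    lengths = catalog.set_index("gene_id")["length_nt"].reindex(de.index)
    lfc = de["log2fc"]
    ok = np.isfinite(lfc) & lengths.notna()
    if ok.sum() < 3:
        raise ValueError("need at least 3 genes with finite log2fc")
    x = np.log10(lengths[ok].to_numpy(dtype=float))
    y = lfc[ok].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("transcript lengths have zero variance")
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), 0.0
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)
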