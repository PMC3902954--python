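"""End-to-end simulation studies of the two filtering strategies.

Each study builds a tissue mixture, simulates TRAP-seq libraries, runs the
NB exact-test comparisons and scores the transcriptome and translatome
filters.  The defaults encode the canonical study conditions: a rare
population at f = 0.02 (endothelial-like; maximum theoretical fold change
50) with no translational regulation, and an abundant population at
f = 0.5 (a dominant neural lineage; maximum theoretical fold change 2) with
translational regulation switched on (te_sd = 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import SHORT_NONCODING, generate_catalog
from .de import NBExactTest
from .evaluate import (
    CrossClassification,
    EnrichmentCall,
    TruthMetrics,
    call_enriched,
    cross_classify,
    jaccard,
    length_fc_regression,
    truth_metrics,
    venn_compare,
)
from .mixture import (
    IP_TRANSLATOME,
    TISSUE_TRANSCRIPTOME,
    TISSUE_TRANSLATOME,
    SampleSpec,
    TissueModel,
    expected_profile,
    generate_tissue,
    max_theoretical_fc,
    truth_enrichment,
)
from .quantify import condition_mean_rpkm, rpkm
from .simulate import CountMatrix, SimulationConfig, replicate_sheet, simulate_counts


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(v) for v in rng.integers(0, 2**31 - 1, size=n)]


def build_study_counts(
    seed: int,
    n_genes: int = 5000,
    f_target: float = 0.02,
    n_markers: int = 300,
    marker_effect: float = 8.0,
    background: float = 0.05,
    depth: int = 2_000_000,
    replicates: int = 3,
    dispersion: float = 0.05,
    te_sd: float = 0.0,
    te_length_slope: float = 0.0,
    biotype_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> tuple[TissueModel, CountMatrix]:
    """Simulate one tissue with transcriptome, translatome and target-IP
    libraries under the given study conditions."""
    catalog_seed, tissue_seed, sim_seed = _child_seeds(seed, 3)
    catalog = generate_catalog(
        n_genes, biotype_fractions=biotype_fractions, seed=catalog_seed
    )
    tissue = generate_tissue(
        catalog,
        {"target": f_target, "rest": 1.0 - f_target},
        n_marker_genes=n_markers,
        marker_effect=marker_effect,
        te_sd=te_sd,
        te_length_slope=te_length_slope,
        seed=tissue_seed,
    )
    conditions = [
        SampleSpec("transcriptome", TISSUE_TRANSCRIPTOME, depth),
        SampleSpec("translatome", TISSUE_TRANSLATOME, depth),
        SampleSpec("ip", IP_TRANSLATOME, depth, target_population="target",
                   background=background),
    ]
    sheet = replicate_sheet(conditions, replicates)
    counts = simulate_counts(
        tissue, sheet, SimulationConfig(dispersion=dispersion, seed=sim_seed)
    )
    return tissue, counts


@dataclass
class FilterComparisonReport:
    """Dual-filter evaluation of one simulated study."""

    params: dict
    calls: dict[str, EnrichmentCall]
    venn: dict
    jaccard: float
    metrics: dict[str, TruthMetrics]
    cross: CrossClassification
    only_transcriptome_discordant_fraction: float
    divergence_ratio: float
    max_theoretical_fc: float
    de_tables: dict[str, pd.DataFrame] = field(repr=False, default_factory=dict)
    mean_rpkm: pd.DataFrame | None = field(repr=False, default=None)
    truth: pd.DataFrame | None = field(repr=False, default=None)
    sweep: pd.DataFrame | None = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [
            "Dual-filter comparison "
            f"(f = {self.params['f_target']}, "
            f"max theoretical FC = {self.max_theoretical_fc:g})",
            f"  transcriptome filter: {len(self.calls['transcriptome'])} calls, "
            f"sensitivity {self.metrics['transcriptome'].sensitivity:.3f}, "
            f"FDR {self.metrics['transcriptome'].fdr:.3f}",
            f"  translatome filter:   {len(self.calls['translatome'])} calls, "
            f"sensitivity {self.metrics['translatome'].sensitivity:.3f}, "
            f"FDR {self.metrics['translatome'].fdr:.3f}",
            f"  Venn (only-translatome / both / only-transcriptome): "
            f"{self.venn['only_a']} / {self.venn['both']} / {self.venn['only_b']}",
            f"  Jaccard overlap: {self.jaccard:.3f}",
            f"  transcriptome-only calls not confirmed vs translatome: "
            f"{self.only_transcriptome_discordant_fraction:.3f}",
        ]
        return "\n".join(lines)


def evaluate_study(
    tissue: TissueModel,
    counts: CountMatrix,
    fc_min: float = 2.0,
    padj_max: float = 0.001,
    rpkm_floor: float = 1.0,
    target_population: str = "target",
    tau_grid: tuple[float, ...] | None = None,
    params: dict | None = None,
) -> FilterComparisonReport:
    """Dual-filter evaluation of an already-simulated study.

    The IP translatome is compared against both whole-tissue references;
    enrichment calls from each filter are scored against the noiseless
    ground truth, and the transcriptome-only calls are cross-classified
    against the translatome comparison.  When ``tau_grid`` is given, the
    fold-change threshold sweep is included in the report.
    """
    from .evaluate import threshold_sweep

    params = dict(params or {})
    params.setdefault("fc_min", fc_min)
    params.setdefault("padj_max", padj_max)
    params.setdefault("rpkm_floor", rpkm_floor)
    f_target = tissue.population(target_population).fraction
    params.setdefault("f_target", f_target)
    tx = counts.samples_of_kind(TISSUE_TRANSCRIPTOME)
    tl = counts.samples_of_kind(TISSUE_TRANSLATOME)
    ip = counts.samples_of_kind(IP_TRANSLATOME, target=target_population)

    expr = rpkm(counts)
    mean_rpkm = condition_mean_rpkm(expr, counts.condition_of)
    rpkm_tx = mean_rpkm[TISSUE_TRANSCRIPTOME]
    rpkm_tl = mean_rpkm[TISSUE_TRANSLATOME]

    de = {
        "ip_vs_transcriptome": NBExactTest(counts.counts, tx, ip).fit().table,
        "ip_vs_translatome": NBExactTest(counts.counts, tl, ip).fit().table,
        "translatome_vs_transcriptome":
            NBExactTest(counts.counts, tx, tl).fit().table,
    }

    call_tx = call_enriched(
        de["ip_vs_transcriptome"], rpkm_tx, fc_min=fc_min, padj_max=padj_max,
        rpkm_floor=rpkm_floor, reference="transcriptome",
    )
    call_tl = call_enriched(
        de["ip_vs_translatome"], rpkm_tl, fc_min=fc_min, padj_max=padj_max,
        rpkm_floor=rpkm_floor, reference="translatome",
    )
    truth = truth_enrichment(tissue, target_population, fc_threshold=fc_min)
    metrics = {
        "transcriptome": truth_metrics(call_tx, truth["enriched_vs_transcriptome"]),
        "translatome": truth_metrics(call_tl, truth["enriched_vs_translatome"]),
    }
    venn = venn_compare(call_tl, call_tx)  # A = translatome, B = transcriptome
    cross = cross_classify(call_tx, de["ip_vs_translatome"], padj_max=padj_max)

    only_tx = EnrichmentCall(
        genes=venn["only_b_genes"], reference="transcriptome",
        fc_min=fc_min, padj_max=padj_max, rpkm_floor=rpkm_floor,
    )
    if len(only_tx):
        only_cross = cross_classify(
            only_tx, de["ip_vs_translatome"], padj_max=padj_max
        )
        discordant = (
            len(only_cross.not_significant) + len(only_cross.depleted)
        ) / len(only_tx)
    else:
        discordant = 0.0
    divergence_ratio = venn["only_b"] / max(1, venn["both"])

    sweep = None
    if tau_grid is not None:
        sweep = threshold_sweep(
            de["ip_vs_transcriptome"], de["ip_vs_translatome"], rpkm_tx,
            tau_grid=tau_grid, padj_max=padj_max, rpkm_floor=rpkm_floor,
        )

    return FilterComparisonReport(
        params=params,
        calls={"transcriptome": call_tx, "translatome": call_tl},
        venn=venn,
        jaccard=jaccard(call_tx, call_tl),
        metrics=metrics,
        cross=cross,
        only_transcriptome_discordant_fraction=discordant,
        divergence_ratio=divergence_ratio,
        max_theoretical_fc=max_theoretical_fc(f_target),
        de_tables=de,
        mean_rpkm=mean_rpkm,
        truth=truth,
        sweep=sweep,
    )


def filter_comparison_study(
    seed: int,
    f_target: float = 0.02,
    n_genes: int = 5000,
    n_markers: int = 300,
    marker_effect: float = 8.0,
    background: float = 0.05,
    depth: int = 2_000_000,
    replicates: int = 3,
    dispersion: float = 0.05,
    te_sd: float = 0.0,
    te_length_slope: float = 0.0,
    fc_min: float = 2.0,
    padj_max: float = 0.001,
    rpkm_floor: float = 1.0,
    tau_grid: tuple[float, ...] | None = None,
) -> FilterComparisonReport:
    """Simulate one study and run the full dual-filter evaluation.

    Defaults encode the rare-population condition (f = 0.02, 300 planted
    8-fold markers, 5% IP background, 2 million reads per library, 3
    replicates per condition, no translational regulation); the abundant
    condition is the same generator at ``f_target=0.5, te_sd=0.5``.
    """
    params = dict(
        seed=seed, f_target=f_target, n_genes=n_genes, n_markers=n_markers,
        marker_effect=marker_effect, background=background, depth=depth,
        replicates=replicates, dispersion=dispersion, te_sd=te_sd,
        te_length_slope=te_length_slope,
    )
    tissue, counts = build_study_counts(
        seed, n_genes=n_genes, f_target=f_target, n_markers=n_markers,
        marker_effect=marker_effect, background=background, depth=depth,
        replicates=replicates, dispersion=dispersion, te_sd=te_sd,
        te_length_slope=te_length_slope,
    )
    return evaluate_study(
        tissue, counts, fc_min=fc_min, padj_max=padj_max,
        rpkm_floor=rpkm_floor, tau_grid=tau_grid, params=params,
    )


def null_calibration_study(
    seed: int,
    n_genes: int = 2000,
    dispersion: float = 0.1,
    replicates: int = 3,
    depth: int = 1_000_000,
    nominal: float = 0.05,
) -> dict:
    """Type-I error of the exact test on a null comparison.

    Two groups of whole-tissue transcriptome replicates share the same
    expected profile; the empirical fraction of p-values below ``nominal``
    estimates the test's size.
    """
    catalog_seed, tissue_seed, sim_seed = _child_seeds(seed, 3)
    catalog = generate_catalog(n_genes, seed=catalog_seed)
    tissue = generate_tissue(catalog, {"all": 1.0}, seed=tissue_seed)
    sheet = replicate_sheet(
        [
            SampleSpec("groupA", TISSUE_TRANSCRIPTOME, depth),
            SampleSpec("groupB", TISSUE_TRANSCRIPTOME, depth),
        ],
        replicates,
    )
    counts = simulate_counts(
        tissue, sheet, SimulationConfig(dispersion=dispersion, seed=sim_seed)
    )
    group_a = [s.sample_id for s in sheet if s.sample_id.startswith("groupA")]
    group_b = [s.sample_id for s in sheet if s.sample_id.startswith("groupB")]
    table = NBExactTest(counts.counts, group_a, group_b).fit().table
    rate = float((table["pval"] < nominal).mean())
    return {"type_i_error": rate, "nominal": nominal, "n_genes": n_genes,
            "table": table}


def noncoding_depletion_study(
    seed: int,
    n_genes: int = 3000,
    depth: int = 2_000_000,
    replicates: int = 3,
    dispersion: float = 0.05,
    min_expected_count: float = 100.0,
) -> dict:
    """Depletion of short noncoding RNAs from the tissue translatome.

    Among short noncoding genes whose expected transcriptome count is at
    least ``min_expected_count``, report the fraction with negative log2
    fold change (translatome over transcriptome).  These RNAs are not
    ribosome-bound, so TRAP should deplete essentially all of them.
    """
    catalog_seed, tissue_seed, sim_seed = _child_seeds(seed, 3)
    catalog = generate_catalog(
        n_genes, biotype_fractions=(0.7, 0.2, 0.1), seed=catalog_seed
    )
    tissue = generate_tissue(catalog, {"all": 1.0}, te_sd=0.3, seed=tissue_seed)
    sheet = replicate_sheet(
        [
            SampleSpec("transcriptome", TISSUE_TRANSCRIPTOME, depth),
            SampleSpec("translatome", TISSUE_TRANSLATOME, depth),
        ],
        replicates,
    )
    counts = simulate_counts(
        tissue, sheet, SimulationConfig(dispersion=dispersion, seed=sim_seed)
    )
    tx = counts.samples_of_kind(TISSUE_TRANSCRIPTOME)
    tl = counts.samples_of_kind(TISSUE_TRANSLATOME)
    table = NBExactTest(counts.counts, tx, tl).fit().table

    q_tx = expected_profile(
        tissue, SampleSpec("expected", TISSUE_TRANSCRIPTOME, depth)
    )
    expected_counts = pd.Series(depth * q_tx, index=tissue.gene_ids)
    short = catalog.set_index("gene_id")["biotype"] == SHORT_NONCODING
    eligible = short & (expected_counts >= min_expected_count)
    if not eligible.any():
        raise ValueError("no well-expressed short noncoding genes in this run")
    depleted = float((table.loc[eligible[eligible].index, "log2fc"] < 0).mean())
    return {
        "fraction_depleted": depleted,
        "n_eligible": int(eligible.sum()),
        "table": table,
    }


def length_trend_study(
    seed: int,
    n_genes: int = 2000,
    te_length_slope: float = -0.5,
    te_sd: float = 0.5,
    depth: int = 2_000_000,
    replicates: int = 3,
    dispersion: float = 0.05,
) -> dict:
    """Recover the transcript-length / translatome-enrichment trend.

    With shorter transcripts translated more efficiently
    (``te_length_slope`` < 0), the regression of translatome-versus-
    transcriptome log2 fold change on log10 length should have a negative
    slope.
    """
    catalog_seed, tissue_seed, sim_seed = _child_seeds(seed, 3)
    catalog = generate_catalog(n_genes, seed=catalog_seed)
    tissue = generate_tissue(
        catalog, {"all": 1.0}, te_sd=te_sd, te_length_slope=te_length_slope,
        seed=tissue_seed,
    )
    sheet = replicate_sheet(
        [
            SampleSpec("transcriptome", TISSUE_TRANSCRIPTOME, depth),
            SampleSpec("translatome", TISSUE_TRANSLATOME, depth),
        ],
        replicates,
    )
    counts = simulate_counts(
        tissue, sheet, SimulationConfig(dispersion=dispersion, seed=sim_seed)
    )
    tx = counts.samples_of_kind(TISSUE_TRANSCRIPTOME)
    tl = counts.samples_of_kind(TISSUE_TRANSLATOME)
    table = NBExactTest(counts.counts, tx, tl).fit().table
    slope, intercept, r = length_fc_regression(table, catalog)
    return {"slope": slope, "intercept": intercept, "r": r, "table": table}


def mixture_bound_check(
    seed: int,
    n_models: int = 1000,
    n_genes: int = 50,
    max_populations: int = 4,
) -> dict:
    """Verify the 1/f bound over random tissue mixtures.

    For random tissues with uniform translation efficiency, no gene's
    noiseless ideal-IP (β = 0) versus tissue-translatome fold change can
    exceed 1/f of the target population.  Returns the largest observed
    excess over the bound (should be <= ~1e-9, i.e. numerical noise only).
    """
    rng = np.random.default_rng(seed)
    catalog = generate_catalog(
        n_genes, biotype_fractions=(1.0, 0.0, 0.0), seed=int(rng.integers(2**31))
    )
    max_excess = -np.inf
    for _ in range(n_models):
        n_pop = int(rng.integers(2, max_populations + 1))
        fractions = rng.dirichlet(np.ones(n_pop))
        from .mixture import PopulationProfile  # local to keep namespace tidy

        pops = [
            PopulationProfile(
                name=f"p{i}",
                fraction=float(f),
                transcription=rng.lognormal(0.0, 1.0, size=n_genes),
                translation_efficiency=np.ones(n_genes),
            )
            for i, f in enumerate(fractions)
        ]
        tissue = TissueModel(catalog=catalog, populations=pops)
        target = pops[0].name
        ip = expected_profile(
            tissue,
            SampleSpec("ip", IP_TRANSLATOME, 1, target_population=target),
        )
        tl = expected_profile(tissue, SampleSpec("tl", TISSUE_TRANSLATOME, 1))
        ratio = np.max(ip / tl)
        excess = ratio - max_theoretical_fc(float(fractions[0]))
        max_excess = max(max_excess, float(excess))
    return {"max_excess": max_excess, "n_models": n_models}
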