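"""End-to-end orchestration: simulate → quantify → test → evaluate.

:func:`run_pipeline` executes one full study from a :class:`RunConfig`,
writing every intermediate (catalog, sample sheet, counts, truth, RPKM,
size factors, three DE tables) and a JSON evaluation report; outputs are
deterministic for a fixed config.  :func:`make_fixtures` writes the tiny
worked tables used throughout the test suite.
"""

from __future__ import annotations

import json
import logging
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .benchmarks import build_study_counts, evaluate_study
from .catalog import generate_catalog
from .config import RunConfig
from .mixture import truth_enrichment
from .quantify import rpkm, size_factors

log = logging.getLogger("trapfe")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict[str, Path]:
    """Run the full study described by ``config`` into ``out_dir``.

    Returns a mapping of artifact names to file paths.  Any stage failure
    raises with the stage name attached.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    sim = config.simulation
    thr = config.thresholds
    log.info("master seed: %d", config.seed)
    log.info("resolved config: %s", json.dumps(config.model_dump(mode="json")))

    stage = "simulate"
    try:
        tissue, counts = build_study_counts(
            config.seed,
            n_genes=sim.n_genes,
            f_target=sim.target_fraction,
            n_markers=sim.n_markers,
            marker_effect=sim.marker_effect,
            background=sim.background,
            depth=sim.depth,
            replicates=sim.replicates,
            dispersion=sim.dispersion,
            te_sd=sim.te_sd,
            te_length_slope=sim.te_length_slope,
            biotype_fractions=sim.biotype_fractions,
        )
        truth = truth_enrichment(tissue, "target", fc_threshold=thr.fc_min)
        paths["catalog"] = out / "catalog.tsv"
        io.write_catalog(tissue.catalog, paths["catalog"])
        paths["sample_sheet"] = out / "sample_sheet.tsv"
        io.write_sample_sheet(counts.samples, paths["sample_sheet"])
        paths["counts"] = out / "counts.tsv"
        io.write_counts_frame(counts.counts, paths["counts"])
        paths["truth"] = out / "truth.tsv"
        io.write_table(truth, paths["truth"])

        stage = "quantify"
        paths["rpkm"] = out / "rpkm.tsv"
        io.write_table(rpkm(counts), paths["rpkm"])
        paths["size_factors"] = out / "size_factors.tsv"
        size_factors(counts).to_frame().to_csv(paths["size_factors"], sep="\t")

        stage = "detest+evaluate"
        report = evaluate_study(
            tissue,
            counts,
            fc_min=thr.fc_min,
            padj_max=thr.padj_max,
            rpkm_floor=thr.rpkm_floor,
            tau_grid=thr.tau_grid(),
            params={"seed": config.seed},
        )
        for name, table in report.de_tables.items():
            paths[f"de_{name}"] = out / f"de_{name}.tsv"
            io.write_de_table(table, paths[f"de_{name}"])
        for name, call in report.calls.items():
            paths[f"call_{name}"] = out / f"call_{name}.tsv"
            pd.Series(call.genes, name="gene_id").to_csv(
                paths[f"call_{name}"], sep="\t", index=False
            )

        stage = "report"
        report_json = {
            "seed": config.seed,
            "version": _pkg_version("trapfe"),
            "config": config.model_dump(mode="json"),
            "max_theoretical_fc": report.max_theoretical_fc,
            "venn": {
                "only_translatome": report.venn["only_a"],
                "both": report.venn["both"],
                "only_transcriptome": report.venn["only_b"],
            },
            "jaccard": report.jaccard,
            "cross_classification": report.cross.counts,
            "only_transcriptome_discordant_fraction":
                report.only_transcriptome_discordant_fraction,
            "divergence_ratio": report.divergence_ratio,
            "truth_metrics": {
                name: {
                    "tp": m.tp, "fp": m.fp, "fn": m.fn, "tn": m.tn,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "fdr": m.fdr,
                }
                for name, m in report.metrics.items()
            },
            "sweep": report.sweep.to_dict(orient="list"),
        }
        paths["report"] = out / "report.json"
        paths["report"].write_text(
            json.dumps(report_json, indent=2, default=_json_default),
            encoding="utf-8",
        )
        paths["sweep"] = out / "sweep.tsv"
        report.sweep.to_csv(paths["sweep"], sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001 - annotate failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return paths


def make_fixtures(out_dir: str | Path, scale: str = "tiny") -> dict[str, Path]:
    """Write small worked fixture tables (catalog, counts, sample sheet).

    ``tiny`` writes a 6-gene, 4-sample set; ``small`` a 12-gene, 8-sample
    set.  Regeneration with the same scale is byte-identical.
    """
    if scale not in ("tiny", "small"):
        raise ValueError(f"scale must be 'tiny' or 'small', got {scale!r}")
    n_genes, n_samples = (6, 4) if scale == "tiny" else (12, 8)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog = generate_catalog(
        n_genes, biotype_fractions=(0.5, 0.25, 0.25), seed=7
    )
    rng = np.random.default_rng(11)
    counts = pd.DataFrame(
        rng.integers(0, 500, size=(n_genes, n_samples)),
        index=pd.Index(catalog["gene_id"], name="gene_id"),
        columns=[f"s{i + 1}" for i in range(n_samples)],
    )
    paths = {
        "catalog": out / f"catalog_{scale}.tsv",
        "counts": out / f"counts_{scale}.tsv",
    }
    io.write_catalog(catalog, paths["catalog"])
    io.write_counts_frame(counts, paths["counts"])
    return paths
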