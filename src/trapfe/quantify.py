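"""Normalisation and expression summaries.

Size factors follow the median-of-ratios estimator: for each gene with
strictly positive counts in every sample, form the ratio of its count to
its geometric mean across samples; a sample's size factor is the median of
these ratios.  RPKM uses the total catalog-assigned reads of the sample as
its per-million denominator (the only depth observable in a count-level
artifact).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .catalog import validate_catalog
from .simulate import CountMatrix


def _counts_frame(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    if isinstance(counts, CountMatrix):
        return counts.counts
    return counts


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, one per sample.

    Only genes with strictly positive counts in every sample enter the
    reference (their geometric mean); the median uses the midpoint
    convention (average of the two central order statistics for even
    counts).  No rescaling is applied afterwards.
    """
    k = _counts_frame(counts)
    values = k.to_numpy(dtype=float)
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "size factors undefined: no gene has positive counts in all samples"
        )
    ref = values[positive]
    log_geo_mean = np.log(ref).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(ref) - log_geo_mean)
    s = np.median(ratios, axis=0)
    return pd.Series(s, index=k.columns, name="size_factor")


def normalized_counts(
    counts: CountMatrix | pd.DataFrame, s: pd.Series
) -> pd.DataFrame:
    """Counts divided column-wise by their size factors."""
    k = _counts_frame(counts)
    s = s.reindex(k.columns)
    if s.isna().any() or (s <= 0).any():
        raise ValueError("size factors must be positive for every sample")
    return k / s


def rpkm(
    counts: CountMatrix | pd.DataFrame,
    catalog: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Reads per kilobase of transcript per million counted reads.

    RPKM_ij = k_ij · 10^9 / (length_i · D_j) with D_j the sample's total
    gene-assigned reads.
    """
    if catalog is None:
        if not isinstance(counts, CountMatrix):
            raise ValueError("catalog required when counts is a bare DataFrame")
        catalog = counts.catalog
    validate_catalog(catalog)
    k = _counts_frame(counts)
    lengths = catalog.set_index("gene_id")["length_nt"].reindex(k.index)
    if lengths.isna().any():
        missing = k.index[lengths.isna()][0]
        raise ValueError(f"gene {missing!r} missing from catalog")
    depth = k.sum(axis=0)
    if (depth == 0).any():
        bad = depth.index[depth == 0][0]
        raise ValueError(f"sample {bad!r} has zero total counts")
    out = k.mul(1e9 / lengths.to_numpy(), axis=0).div(depth, axis=1)
    out.attrs["denominator"] = "catalog_assigned_reads"
    return out


def condition_mean_rpkm(
    expr: pd.DataFrame, groups: dict[str, str]
) -> pd.DataFrame:
    """Arithmetic mean expression per condition.

    ``groups`` maps sample_id -> condition label; every condition must have
    at least one sample present in ``expr``.
    """
    cond_samples: dict[str, list[str]] = {}
    for sample, cond in groups.items():
        cond_samples.setdefault(cond, []).append(sample)
    out = {}
    for cond, samples in cond_samples.items():
        present = [s for s in samples if s in expr.columns]
        if not present:
            raise ValueError(f"condition {cond!r} has no samples in the matrix")
        out[cond] = expr[present].mean(axis=1)
    return pd.DataFrame(out)
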