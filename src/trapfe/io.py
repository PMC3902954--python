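"""Tab-separated file formats for catalogs, sample sheets, counts, truth
tables and DE results.

All files are UTF-8, tab-separated with a header row, "." decimal and
"inf"/"nan" literals; CRLF input parses identically to LF.  Integer counts
round-trip exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import validate_catalog
from .mixture import SampleSpec
from .simulate import CountMatrix

DE_COLUMNS = [
    "base_mean_A", "base_mean_B", "fold_change", "log2fc", "pval", "padj",
]

SAMPLE_SHEET_COLUMNS = [
    "sample_id", "kind", "target_population", "background",
    "library_size", "replicate",
]


def read_catalog(path: str | Path) -> pd.DataFrame:
    catalog = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    catalog["length_nt"] = catalog["length_nt"].astype(int)
    return validate_catalog(catalog)


def write_catalog(catalog: pd.DataFrame, path: str | Path) -> None:
    validate_catalog(catalog)
    catalog.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> list[SampleSpec]:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    specs = []
    for row in frame.itertuples(index=False):
        target = row.target_population
        if pd.isna(target) or target == "":
            target = None
        background = 0.0 if pd.isna(row.background) else float(row.background)
        specs.append(
            SampleSpec(
                sample_id=row.sample_id,
                kind=row.kind,
                library_size=int(row.library_size),
                replicate=int(row.replicate),
                target_population=target,
                background=background,
            )
        )
    return specs


def write_sample_sheet(samples: list[SampleSpec], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "kind": s.kind,
                "target_population": s.target_population or "",
                "background": s.background if s.kind == "ip_translatome" else "",
                "library_size": s.library_size,
                "replicate": s.replicate,
            }
            for s in samples
        ],
        columns=SAMPLE_SHEET_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)


def read_counts_frame(path: str | Path) -> pd.DataFrame:
    """Read a count-matrix TSV (first column gene_id, integer cells)."""
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if frame.columns[0] != "gene_id":
        raise ValueError("count matrix must start with a gene_id column")
    dup = frame["gene_id"][frame["gene_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene_id in count matrix: {dup.iloc[0]!r}")
    frame = frame.set_index("gene_id")
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if not np.all(values == np.rint(values)):
            raise ValueError("count matrix contains non-integer cells")
        frame = frame.astype(np.int64)
    if (frame.to_numpy() < 0).any():
        raise ValueError("count matrix contains negative cells")
    return frame


def write_counts_frame(counts: pd.DataFrame, path: str | Path) -> None:
    out = counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_count_matrix(
    counts_path: str | Path,
    sample_sheet_path: str | Path,
    catalog_path: str | Path,
) -> CountMatrix:
    return CountMatrix(
        counts=read_counts_frame(counts_path),
        samples=read_sample_sheet(sample_sheet_path),
        catalog=read_catalog(catalog_path),
    )


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a gene-indexed numeric TSV (RPKM, DE results, truth table)."""
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    out = frame.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    write_table(de[DE_COLUMNS], path)


def read_de_table(path: str | Path) -> pd.DataFrame:
    de = read_table(path)
    missing = set(DE_COLUMNS) - set(de.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    return de
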