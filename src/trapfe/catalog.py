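"""Gene catalogs: identifiers, transcript lengths and biotypes.

A catalog is carried as a :class:`pandas.DataFrame` with columns
``gene_id`` (unique), ``length_nt`` (int, >= 1) and ``biotype`` (one of
:data:`BIOTYPES`).  Short noncoding genes (miRNA/snoRNA-like) are never
translated downstream; transcript length drives RPKM and the
length/enrichment regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CODING = "coding"
SHORT_NONCODING = "short_noncoding"
LONG_NONCODING = "long_noncoding"
BIOTYPES = (CODING, SHORT_NONCODING, LONG_NONCODING)

#: Default log-normal length laws per biotype, (mu, sigma) of ln(length in nt).
#: Coding transcripts centre around ~2 kb, short noncoding RNAs around ~100 nt,
#: long noncoding RNAs around ~1.5 kb.
DEFAULT_LENGTH_LAWS: dict[str, tuple[float, float]] = {
    CODING: (np.log(2000.0), 0.7),
    SHORT_NONCODING: (np.log(100.0), 0.5),
    LONG_NONCODING: (np.log(1500.0), 0.8),
}

CATALOG_COLUMNS = ("gene_id", "length_nt", "biotype")


@dataclass(frozen=True)
class GeneRecord:
    """A single catalog entry."""

    gene_id: str
    length_nt: int
    biotype: str

    def __post_init__(self) -> None:
        if self.length_nt < 1:
            raise ValueError(f"length_nt must be >= 1, got {self.length_nt}")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")


def validate_catalog(catalog: pd.DataFrame) -> pd.DataFrame:
    """Check catalog invariants and return the frame unchanged."""
    missing = set(CATALOG_COLUMNS) - set(catalog.columns)
    if missing:
        raise ValueError(f"catalog missing columns: {sorted(missing)}")
    dup = catalog["gene_id"][catalog["gene_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene_id in catalog: {dup.iloc[0]!r}")
    if (catalog["length_nt"] < 1).any():
        raise ValueError("catalog contains length_nt < 1")
    bad = set(catalog["biotype"]) - set(BIOTYPES)
    if bad:
        raise ValueError(f"unknown biotypes in catalog: {sorted(bad)}")
    return catalog


def _largest_remainder_counts(n: int, fractions: np.ndarray) -> np.ndarray:
    """Apportion ``n`` items to classes by largest-remainder rounding."""
    quotas = n * fractions
    counts = np.floor(quotas).astype(int)
    remainder = int(n - counts.sum())
    if remainder > 0:
        order = np.argsort(-(quotas - counts), kind="stable")
        counts[order[:remainder]] += 1
    return counts


def generate_catalog(
    n_genes: int,
    biotype_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    length_laws: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a synthetic gene catalog.

    Parameters
    ----------
    n_genes
        Number of genes (>= 2).
    biotype_fractions
        Fractions of (coding, short_noncoding, long_noncoding) genes; must
        sum to 1.  Counts are apportioned by largest-remainder rounding.
    length_laws
        Per-biotype ``(mu, sigma)`` of the log-normal transcript-length law
        (natural log of length in nt); defaults to
        :data:`DEFAULT_LENGTH_LAWS`.  Lengths are rounded and clipped at 1 nt.
    seed
        Seed for the length draws; identical inputs give identical catalogs.
    """
    if n_genes < 2:
        raise ValueError(f"n_genes must be >= 2, got {n_genes}")
    fractions = np.asarray(biotype_fractions, dtype=float)
    if fractions.shape != (3,) or (fractions < 0).any() or (fractions > 1).any():
        raise ValueError("biotype_fractions must be three values in [0, 1]")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError(f"biotype_fractions must sum to 1, got {fractions.sum()}")
    laws = dict(DEFAULT_LENGTH_LAWS)
    if length_laws:
        laws.update(length_laws)

    counts = _largest_remainder_counts(n_genes, fractions)
    rng = np.random.default_rng(seed)
    biotypes: list[str] = []
    lengths: list[np.ndarray] = []
    for biotype, count in zip(BIOTYPES, counts):
        biotypes.extend([biotype] * int(count))
        mu, sigma = laws[biotype]
        ln = rng.lognormal(mean=mu, sigma=sigma, size=int(count))
        lengths.append(np.maximum(1, np.rint(ln)).astype(int))
    width = len(str(n_genes - 1))
    catalog = pd.DataFrame(
        {
            "gene_id": [f"gene_{i:0{width}d}" for i in range(n_genes)],
            "length_nt": np.concatenate(lengths) if lengths else np.array([], int),
            "biotype": biotypes,
        }
    )
    return validate_catalog(catalog)
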