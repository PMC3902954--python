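"""Tissue as a mixture of cell populations, and expected TRAP-seq profiles.

The generative model: a tissue is a set of cell populations with fractions
``f_p`` summing to 1.  Each population has a per-gene transcription level
``x_pg`` (arbitrary units per cell) and a per-gene translation efficiency
``t_pg`` (zero for short noncoding RNAs, which are not ribosome-bound).
Populations are assumed to contribute equal total RNA per cell, so each
population's ``x`` vector is compared after normalisation to unit sum; a
per-population ``rna_content`` multiplier is exposed for sensitivity
analysis.

Three sample kinds are modelled:

``tissue_transcriptome``
    total RNA of the whole tissue, q ∝ Σ_p f_p x̂_pg
``tissue_translatome``
    ribosome-bound RNA of the whole tissue (pan-cellular TRAP),
    q ∝ Σ_p f_p x̂_pg t_pg
``ip_translatome``
    TRAP from one target population, contaminated by a fraction ``β`` of
    nonspecifically captured tissue-translatome material:
    q ∝ (1−β)·normalise(x̂_target t_target) + β·normalise(Σ_p f_p x̂ t)

For a transcript expressed exclusively in a target population that makes up
a fraction ``f`` of the tissue, the IP-versus-tissue fold change cannot
exceed ``1/f`` under uniform translation efficiency — the maximum
theoretical fold change that separates rare populations (large 1/f) from
abundant ones (1/f around two).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import SHORT_NONCODING, CODING, validate_catalog

TISSUE_TRANSCRIPTOME = "tissue_transcriptome"
TISSUE_TRANSLATOME = "tissue_translatome"
IP_TRANSLATOME = "ip_translatome"
SAMPLE_KINDS = (TISSUE_TRANSCRIPTOME, TISSUE_TRANSLATOME, IP_TRANSLATOME)


@dataclass
class PopulationProfile:
    """One cell population of a tissue mixture.

    ``transcription`` and ``translation_efficiency`` are per-gene arrays
    aligned with the tissue's catalog.  ``rna_content`` scales the
    population's total RNA per cell relative to the others (default 1:
    equal total RNA per cell).
    """

    name: str
    fraction: float
    transcription: np.ndarray
    translation_efficiency: np.ndarray
    rna_content: float = 1.0

    def __post_init__(self) -> None:
        self.transcription = np.asarray(self.transcription, dtype=float)
        self.translation_efficiency = np.asarray(
            self.translation_efficiency, dtype=float
        )
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError(f"fraction must be in (0, 1], got {self.fraction}")
        if (self.transcription < 0).any() or (self.translation_efficiency < 0).any():
            raise ValueError("transcription and translation efficiency must be >= 0")
        if not (self.transcription > 0).any():
            raise ValueError("population must transcribe at least one gene")
        if self.rna_content <= 0:
            raise ValueError("rna_content must be > 0")


@dataclass
class TissueModel:
    """A catalog plus the populations mixed into one tissue."""

    catalog: pd.DataFrame
    populations: list[PopulationProfile]
    #: marker gene ids per population name (set by :func:`generate_tissue`)
    markers: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_catalog(self.catalog)
        n = len(self.catalog)
        for pop in self.populations:
            if len(pop.transcription) != n or len(pop.translation_efficiency) != n:
                raise ValueError(
                    f"population {pop.name!r} profiles do not match catalog size {n}"
                )
        total = sum(p.fraction for p in self.populations)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"population fractions must sum to 1, got {total}")
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("population names must be unique")
        short = self.catalog["biotype"].to_numpy() == SHORT_NONCODING
        for pop in self.populations:
            if (pop.translation_efficiency[short] != 0).any():
                raise ValueError(
                    f"population {pop.name!r} has nonzero translation efficiency "
                    "for short_noncoding genes"
                )

    def population(self, name: str) -> PopulationProfile:
        for pop in self.populations:
            if pop.name == name:
                return pop
        raise KeyError(f"no population named {name!r}")

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.catalog["gene_id"])


@dataclass
class SampleSpec:
    """Declared identity of one sequencing library."""

    sample_id: str
    kind: str
    library_size: int
    replicate: int = 1
    target_population: str | None = None
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in SAMPLE_KINDS:
            raise ValueError(f"unknown sample kind {self.kind!r}")
        if self.kind == IP_TRANSLATOME and not self.target_population:
            raise ValueError("ip_translatome samples need a target_population")
        if self.kind != IP_TRANSLATOME and self.target_population:
            raise ValueError(
                f"target_population is only meaningful for ip_translatome samples "
                f"(sample {self.sample_id!r})"
            )
        if not (0.0 <= self.background <= 1.0):
            raise ValueError(f"background must be in [0, 1], got {self.background}")
        if self.library_size < 1:
            raise ValueError("library_size must be >= 1")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")


def _normalize(v: np.ndarray, what: str) -> np.ndarray:
    total = v.sum()
    if total <= 0:
        raise ValueError(f"{what} profile is all zero and cannot be normalised")
    return v / total


def _population_rna(pop: PopulationProfile) -> np.ndarray:
    """Per-gene RNA amount per cell: normalised transcription × rna_content."""
    return pop.rna_content * _normalize(pop.transcription, f"population {pop.name!r}")


def _tissue_transcriptome(tissue: TissueModel) -> np.ndarray:
    return sum(p.fraction * _population_rna(p) for p in tissue.populations)


def _tissue_translatome_raw(tissue: TissueModel) -> np.ndarray:
    return sum(
        p.fraction * _population_rna(p) * p.translation_efficiency
        for p in tissue.populations
    )


def expected_profile(tissue: TissueModel, spec: SampleSpec) -> np.ndarray:
    """Noiseless relative-abundance profile ``q`` (sums to 1) for one sample.

    ``ip_translatome`` profiles are the convex combination of the target
    population's own translatome (weight 1−β) and the whole-tissue
    translatome (weight β, the nonspecific background).
    """
    if spec.kind == TISSUE_TRANSCRIPTOME:
        return _normalize(_tissue_transcriptome(tissue), "tissue transcriptome")
    if spec.kind == TISSUE_TRANSLATOME:
        return _normalize(_tissue_translatome_raw(tissue), "tissue translatome")
    target = tissue.population(spec.target_population)
    own = _normalize(
        _population_rna(target) * target.translation_efficiency,
        f"target {target.name!r} translatome",
    )
    beta = spec.background
    if beta == 0.0:
        return own
    tissue_tl = _normalize(_tissue_translatome_raw(tissue), "tissue translatome")
    return (1.0 - beta) * own + beta * tissue_tl


def max_theoretical_fc(f: float) -> float:
    """Maximum theoretical IP-vs-tissue fold change for a population at
    fraction ``f``.

    Under equal total RNA per cell and uniform translation efficiency, a
    transcript expressed exclusively in the target population can be at most
    ``1/f``-fold enriched in the IP over the whole tissue; for an abundant
    lineage at f = 0.5 the bound is only 2, while rare populations admit
    much larger fold changes.
    """
    if not (0.0 < f <= 1.0):
        raise ValueError(f"population fraction must be in (0, 1], got {f}")
    return 1.0 / f


def generate_tissue(
    catalog: pd.DataFrame,
    population_fractions: dict[str, float],
    n_marker_genes: int = 0,
    marker_effect: float = 8.0,
    te_sd: float = 0.0,
    te_length_slope: float = 0.0,
    transcription_sigma: float = 1.2,
    seed: int = 0,
) -> TissueModel:
    """Generate a tissue mixture with planted population markers.

    Baseline transcription is log-normal (sigma ``transcription_sigma``)
    shared across populations; each population then receives
    ``n_marker_genes`` disjoint coding marker genes whose transcription is
    ``marker_effect``-fold the baseline in that population only.

    Translation efficiency is drawn once per gene (shared across
    populations): ``ln t = te_length_slope · (log10 L − mean log10 L) + ε``
    with ``ε ~ Normal(0, te_sd)``, then forced to 0 for short noncoding
    genes.  ``te_sd = 0`` with ``te_length_slope = 0`` gives uniform
    translation (no translational regulation); a negative slope makes
    shorter transcripts better translated.
    """
    validate_catalog(catalog)
    fractions = dict(population_fractions)
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"population fractions must sum to 1, got {total}")
    if n_marker_genes and marker_effect <= 1.0:
        raise ValueError(f"marker_effect must be > 1, got {marker_effect}")
    if te_sd < 0:
        raise ValueError("te_sd must be >= 0")

    n = len(catalog)
    coding_idx = np.flatnonzero(catalog["biotype"].to_numpy() == CODING)
    if n_marker_genes * len(fractions) > len(coding_idx):
        raise ValueError(
            f"{n_marker_genes} markers x {len(fractions)} populations exceed "
            f"the {len(coding_idx)} coding genes available"
        )

    rng = np.random.default_rng(seed)
    baseline = rng.lognormal(mean=0.0, sigma=transcription_sigma, size=n)

    log10_len = np.log10(catalog["length_nt"].to_numpy(dtype=float))
    ln_t = te_length_slope * (log10_len - log10_len.mean())
    if te_sd > 0:
        ln_t = ln_t + rng.normal(0.0, te_sd, size=n)
    t = np.exp(ln_t)
    t[catalog["biotype"].to_numpy() == SHORT_NONCODING] = 0.0

    marker_pool = rng.permutation(coding_idx)
    populations: list[PopulationProfile] = []
    markers: dict[str, list[str]] = {}
    gene_ids = catalog["gene_id"].to_numpy()
    for i, (name, f) in enumerate(fractions.items()):
        x = baseline.copy()
        idx = marker_pool[i * n_marker_genes : (i + 1) * n_marker_genes]
        x[idx] *= marker_effect
        markers[name] = list(gene_ids[idx])
        populations.append(
            PopulationProfile(
                name=name,
                fraction=f,
                transcription=x,
                translation_efficiency=t.copy(),
            )
        )
    return TissueModel(catalog=catalog, populations=populations, markers=markers)


def truth_enrichment(
    tissue: TissueModel,
    target_population: str,
    fc_threshold: float = 2.0,
) -> pd.DataFrame:
    """Ground-truth enrichment of the target population's ideal IP.

    True fold changes are ratios of noiseless expected profiles with β = 0
    (ideal IP) over each whole-tissue reference.  Genes present in the
    target but absent from a reference get a ``+inf`` sentinel; genes absent
    from the target get 0.  ``enriched_vs_*`` is true iff the true fold
    change strictly exceeds ``fc_threshold``.

    Returns a frame indexed by gene_id with columns
    ``true_fc_vs_transcriptome``, ``true_fc_vs_translatome``,
    ``enriched_vs_transcriptome``, ``enriched_vs_translatome``.
    """
    if fc_threshold <= 1.0:
        raise ValueError(f"fc_threshold must be > 1, got {fc_threshold}")
    ip = expected_profile(
        tissue,
        SampleSpec("truth_ip", IP_TRANSLATOME, library_size=1,
                   target_population=target_population, background=0.0),
    )
    out = {}
    for ref_name, kind in (
        ("transcriptome", TISSUE_TRANSCRIPTOME),
        ("translatome", TISSUE_TRANSLATOME),
    ):
        ref = expected_profile(tissue, SampleSpec("truth_ref", kind, library_size=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = np.where(ref > 0, ip / np.where(ref > 0, ref, 1.0),
                          np.where(ip > 0, np.inf, 0.0))
        out[f"true_fc_vs_{ref_name}"] = fc
        out[f"enriched_vs_{ref_name}"] = fc > fc_threshold
    frame = pd.DataFrame(out, index=tissue.gene_ids)
    frame.index.name = "gene_id"
    frame.attrs["target_population"] = target_population
    frame.attrs["fc_threshold"] = fc_threshold
    return frame
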