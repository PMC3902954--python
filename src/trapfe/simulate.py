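"""Negative-binomial count simulation from expected tissue profiles.

Counts for sample ``j`` are drawn gene-wise independent with mean
``μ = N_j q_g`` (library size times relative abundance) and variance
``μ + α μ²``; ``α = 0`` degenerates to Poisson.  One master seed spawns a
child stream per sample in sample-sheet order, so appending a sample never
perturbs the counts of earlier samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixture import SampleSpec, TissueModel, expected_profile


@dataclass
class SimulationConfig:
    """Noise model and reproducibility contract for one simulation.

    ``dispersion`` is the NB over-dispersion α (scalar, or per-gene array
    matching the catalog); variance = μ + αμ².
    """

    dispersion: float | np.ndarray = 0.05
    seed: int = 0
    replicates_per_condition: int = 1

    def __post_init__(self) -> None:
        alpha = np.asarray(self.dispersion, dtype=float)
        if not np.all(np.isfinite(alpha)) or (alpha < 0).any():
            raise ValueError("dispersion must be finite and >= 0")
        if self.replicates_per_condition < 1:
            raise ValueError("replicates_per_condition must be >= 1")


@dataclass
class CountMatrix:
    """Gene × sample integer counts with their sample sheet and catalog."""

    counts: pd.DataFrame
    samples: list[SampleSpec]
    catalog: pd.DataFrame

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if list(self.counts.columns) != ids:
            raise ValueError("count columns do not match the sample sheet order")
        if not self.counts.index.equals(pd.Index(self.catalog["gene_id"])):
            raise ValueError("count rows do not match the catalog")
        values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValueError("counts must be >= 0")

    def samples_of_kind(self, kind: str, target: str | None = None) -> list[str]:
        out = []
        for s in self.samples:
            if s.kind != kind:
                continue
            if target is not None and s.target_population != target:
                continue
            out.append(s.sample_id)
        return out

    @property
    def condition_of(self) -> dict[str, str]:
        """sample_id -> condition label (kind, plus target for IP samples)."""
        return condition_labels(self.samples)


def condition_labels(samples: list[SampleSpec]) -> dict[str, str]:
    """Map sample ids to condition labels (kind, plus target for IP)."""
    cond = {}
    for s in samples:
        label = s.kind if s.target_population is None else (
            f"{s.kind}:{s.target_population}"
        )
        cond[s.sample_id] = label
    return cond


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Draw NB(mean=mu, var=mu+alpha*mu^2) counts; Poisson where alpha=0."""
    counts = np.zeros(mu.shape, dtype=np.int64)
    pois = (alpha == 0) | (mu == 0)
    if pois.any():
        counts[pois] = rng.poisson(mu[pois])
    nb = ~pois
    if nb.any():
        size = 1.0 / alpha[nb]
        p = size / (size + mu[nb])
        counts[nb] = rng.negative_binomial(size, p)
    return counts


def simulate_counts(
    tissue: TissueModel,
    sample_sheet: list[SampleSpec],
    config: SimulationConfig,
) -> CountMatrix:
    """Simulate a gene × sample count matrix for the given sample sheet."""
    n_genes = len(tissue.catalog)
    alpha = np.broadcast_to(
        np.asarray(config.dispersion, dtype=float), (n_genes,)
    ).copy()
    ids = [s.sample_id for s in sample_sheet]
    if len(set(ids)) != len(ids):
        raise ValueError("sample_ids must be unique")

    children = np.random.SeedSequence(config.seed).spawn(len(sample_sheet))
    columns = {}
    for spec, child in zip(sample_sheet, children):
        q = expected_profile(tissue, spec)
        mu = float(spec.library_size) * q
        if not np.all(np.isfinite(mu)):
            raise ValueError(f"library_size overflow for sample {spec.sample_id!r}")
        rng = np.random.default_rng(child)
        columns[spec.sample_id] = _nb_draw(rng, mu, alpha)
    counts = pd.DataFrame(columns, index=pd.Index(tissue.catalog["gene_id"],
                                                  name="gene_id"))
    return CountMatrix(counts=counts, samples=list(sample_sheet),
                       catalog=tissue.catalog)


def replicate_sheet(
    conditions: list[SampleSpec],
    replicates: int,
) -> list[SampleSpec]:
    """Expand one spec per condition into ``replicates`` numbered samples."""
    sheet = []
    for spec in conditions:
        for r in range(1, replicates + 1):
            sheet.append(
                SampleSpec(
                    sample_id=f"{spec.sample_id}_r{r}",
                    kind=spec.kind,
                    library_size=spec.library_size,
                    replicate=r,
                    target_population=spec.target_population,
                    background=spec.background,
                )
            )
    return sheet
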