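"""Run configuration: one strict YAML/JSON schema for a full pipeline run."""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulationSection(_Strict):
    """Generator settings: the tissue mixture and the sequencing design."""

    n_genes: int = Field(5000, ge=2)
    biotype_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    target_fraction: float = Field(0.02, gt=0.0, le=1.0)
    n_markers: int = Field(300, ge=0)
    marker_effect: float = Field(8.0, gt=1.0)
    te_sd: float = Field(0.0, ge=0.0)
    te_length_slope: float = 0.0
    background: float = Field(0.05, ge=0.0, le=1.0)
    dispersion: float = Field(0.05, ge=0.0)
    depth: int = Field(2_000_000, ge=1)
    replicates: int = Field(3, ge=1)

    @model_validator(mode="after")
    def _check_fractions(self) -> "SimulationSection":
        if abs(sum(self.biotype_fractions) - 1.0) > 1e-9:
            raise ValueError("biotype_fractions must sum to 1")
        return self


class OrganMarkerSection(_Strict):
    fc_between: float = 4.0
    fc_ref: float = 2.0
    rpkm_min: float = 5.0


class ThresholdSection(_Strict):
    """Enrichment-calling thresholds and the fold-change sweep grid."""

    fc_min: float = Field(2.0, ge=0.0)
    padj_max: float = Field(0.001, gt=0.0, le=1.0)
    rpkm_floor: float = Field(1.0, ge=0.0)
    tau_min: float = Field(1.0, gt=0.0)
    tau_max: float = Field(32.0, gt=0.0)
    tau_points: int = Field(40, ge=2)
    organ_markers: OrganMarkerSection = OrganMarkerSection()

    def tau_grid(self) -> tuple[float, ...]:
        import numpy as np

        return tuple(
            np.logspace(
                np.log10(self.tau_min), np.log10(self.tau_max), self.tau_points
            )
        )


class RunConfig(_Strict):
    """Everything one reproducible run needs, serialisable to YAML/JSON."""

    seed: int = 0
    simulation: SimulationSection = SimulationSection()
    thresholds: ThresholdSection = ThresholdSection()

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        if str(path).endswith(".json"):
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        return cls.model_validate(data or {})

    def to_file(self, path: str | Path) -> None:
        data = self.model_dump(mode="json")
        if str(path).endswith(".json"):
            Path(path).write_text(json.dumps(data, indent=2), encoding="utf-8")
        else:
            Path(path).write_text(yaml.safe_dump(data), encoding="utf-8")
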