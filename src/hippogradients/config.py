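"""Validated run configuration for the end-to-end synthetic pipeline.

Defaults are the study conditions of the synthetic analysis: a 32 x 16
flatmap, 200 cortical parcels in 7 networks per species, 10 subjects per
species with 600 time points at unit observation noise, 80% attenuation of
one network's hippocampal coupling in species M, reference diffusion-map
embedding settings (top-10% row sparsity, alpha 0.5), the 16/8 axis
binning, and 1000 spin permutations.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, model_validator

_STRICT = ConfigDict(extra="forbid")


class SimulationConfig(BaseModel):
    model_config = _STRICT
    n_ap: int = Field(32, ge=2)
    n_pd: int = Field(16, ge=2)
    n_parcels: int = Field(200, ge=2)
    n_networks: int = Field(7, ge=1)
    n_subjects: int = Field(10, ge=1)
    n_timepoints: int = Field(600, ge=10)
    noise_sd: float = Field(1.0, ge=0.0)
    divergent_network: int | None = None  # default: last network
    divergence: float = Field(0.8, ge=0.0, le=1.0)
    ar_coef: float = Field(0.0, gt=-1.0, lt=1.0)


class EmbeddingConfig(BaseModel):
    model_config = _STRICT
    sparsity: float = Field(0.9, ge=0.0, lt=1.0)
    alpha: float = Field(0.5, ge=0.0, le=1.0)
    n_components: int = Field(10, ge=1)


class MatchingConfig(BaseModel):
    model_config = _STRICT
    penalty: float = Field(0.1, gt=0.0)
    n_perm: int = Field(1000, ge=1)
    q_grid: tuple[float, ...] = (0.70, 0.75, 0.80, 0.85, 0.90, 0.95)
    correction: str = "bonferroni"


class DualRegConfig(BaseModel):
    model_config = _STRICT
    ap_bins: int = Field(16, ge=2)
    pd_bins: int = Field(8, ge=2)
    exclude: float = Field(0.10, ge=0.0, lt=0.5)


class HomologyConfig(BaseModel):
    model_config = _STRICT
    # Geodesic searchlight radius on the registration sphere, in units of
    # sphere_radius.  The synthetic default yields ~6-9 neighbors out of
    # 200 parcels, keeping searchlights mostly within one network.
    radius: float = Field(0.35, gt=0.0)
    sphere_radius: float = Field(1.0, gt=0.0)


class SubfieldConfig(BaseModel):
    model_config = _STRICT
    boundaries_h: tuple[float, float, float] = (0.25, 0.50, 0.70)
    boundaries_m: tuple[float, float, float] = (0.30, 0.60, 0.80)
    jitter_sd: float = Field(0.02, ge=0.0)


class RunConfig(BaseModel):
    """Schema-validated configuration; unknown keys are rejected."""

    model_config = _STRICT
    seed: int = 0
    out_dir: str = "results/pipeline"
    log_level: str = "INFO"
    simulation: SimulationConfig = SimulationConfig()
    embedding: EmbeddingConfig = EmbeddingConfig()
    matching: MatchingConfig = MatchingConfig()
    dualreg: DualRegConfig = DualRegConfig()
    homology: HomologyConfig = HomologyConfig()
    subfields: SubfieldConfig = SubfieldConfig()

    @model_validator(mode="after")
    def _check(self):
        if self.simulation.divergent_network is not None and not (
            1 <= self.simulation.divergent_network <= self.simulation.n_networks
        ):
            raise ValueError("divergent_network outside 1..n_networks")
        return self

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return self.model_dump(mode="json")
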