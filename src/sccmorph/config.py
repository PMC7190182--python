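"""Validated pipeline configuration (YAML-backed)."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator


class PhantomStudyConfig(BaseModel):
    """Synthetic-cohort stage: an in-silico two-group bilateral study."""

    n_per_group: tuple[int, int] = (2, 2)
    lateral_delta_deg: float = 4.1
    voxel_spacing_mm: float = Field(0.5, gt=0)
    noise_sd: float = Field(5.0, ge=0)
    division_spacing: float = Field(0.7, gt=0)
    refine_iterations: int = Field(0, ge=0)
    supersample: int = Field(1, ge=1)

    @field_validator("n_per_group")
    @classmethod
    def _n_ok(cls, v):
        if min(v) < 1:
            raise ValueError("need at least 1 subject per group")
        return v


class StatsConfig(BaseModel):
    """Statistics stage options."""

    q: float = Field(0.05, gt=0, lt=1)
    curves_csv: str | None = None


class PipelineConfig(BaseModel):
    """Full pipeline run: phantom cohort and/or statistics.

    Either ``phantom`` generates a measurement table through the image
    pipeline, or ``cohort_csv`` names an existing long-format table; the
    statistics stage runs on whichever is available.
    """

    seed: int = 0
    out_dir: str = "sccmorph_out"
    cohort_csv: str | None = None
    phantom: PhantomStudyConfig | None = None
    stats: StatsConfig = StatsConfig()
    run_stats: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.model_validate(doc)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=True)
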