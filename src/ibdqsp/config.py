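"""Run configuration: validated, human-diffable YAML."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

__all__ = ["RunConfig", "load_config"]


class SolverConfig(BaseModel):
    method: str = "LSODA"
    rtol: float = Field(1e-8, gt=0)
    atol: float = Field(1e-10, gt=0)


class BaselineConfig(BaseModel):
    """Lognormal law and statistic kind of the trial baseline fixture."""

    crp_median: float = Field(10.0, gt=0)
    crp_gsd: float = Field(2.5, gt=1)
    fcp_median: float = Field(600.0, gt=0)
    fcp_gsd: float = Field(2.5, gt=1)
    kind: str = "median_iqr"
    tolerance: float = Field(0.15, gt=0, le=0.5)
    fixture_n: int = Field(200, ge=2)

    @field_validator("kind")
    @classmethod
    def _known_kind(cls, v):
        if v not in ("median_iqr", "mean_sd", "median_range"):
            raise ValueError(f"unknown statistic kind {v!r}")
        return v


class CalibrationConfig(BaseModel):
    enabled: bool = True
    params: list[str] = Field(
        default_factory=lambda: ["Kd:PF-04236921", "b_CRP"])
    maxfev: int = Field(40, ge=0)
    n_starts: int = Field(1, ge=1)
    population_size: int = Field(60, ge=2)


class TrialConfig(BaseModel):
    regimen_a: str = "infliximab_induction"
    regimen_b: str = "ustekinumab_6mgkg"
    horizon_days: float = Field(84.0, gt=0)


class RunConfig(BaseModel):
    """Everything a pipeline run needs; every field has a sane default."""

    seed: int = 1
    out_dir: str = "results"
    cohort_size: int = Field(1000, ge=2)
    population_size: int = Field(200, ge=2)
    body_weight_kg: float = Field(70.0, gt=0)
    criterion: str = "crp_below_3"
    solver: SolverConfig = SolverConfig()
    baseline: BaselineConfig = BaselineConfig()
    calibration: CalibrationConfig = CalibrationConfig()
    trial: TrialConfig = TrialConfig()
    kd_nM: dict[str, float] = Field(default_factory=dict)

    def snapshot(self) -> dict:
        return self.model_dump()


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML run configuration (None -> all defaults)."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)
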