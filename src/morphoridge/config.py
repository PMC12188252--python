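"""Validated run configuration (JSON) shared by the CLI subcommands."""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, Field, field_validator

from .energetics import MaterialParams
from .pattern import GrowthSchedule

__all__ = ["MaterialConfig", "ScheduleConfig", "SolverConfig", "RunConfig", "load_config"]


class MaterialConfig(BaseModel):
    m: int = Field(4, ge=2, description="interaction exponent")
    mu: float = Field(10.0, ge=0.0, description="reduced stiffness ratio")
    eta: float = Field(0.0, ge=0.0, description="remodelling relaxation rate")

    def build(self) -> MaterialParams:
        return MaterialParams(m=self.m, mu=self.mu, eta=self.eta)


class ScheduleConfig(BaseModel):
    L0: float = Field(1.0, gt=0.0)
    g: float = Field(1.0, ge=0.0, description="excess growth rate (dimensionless)")
    growth_rate: float = Field(1.0, ge=0.0, description="domain growth rate")
    delta0: float = Field(0.0, ge=0.0, description="initial excess half-length")
    kind: str = "linear"

    @field_validator("kind")
    @classmethod
    def _kind(cls, v: str) -> str:
        if v not in ("linear", "burst"):
            raise ValueError("schedule kind must be 'linear' or 'burst'")
        return v

    def build(self) -> GrowthSchedule:
        return GrowthSchedule(
            L0=self.L0,
            g=self.g,
            growth_rate=self.growth_rate if self.kind == "linear" else 0.0,
            delta0=self.delta0,
            kind=self.kind,
        )


class SolverConfig(BaseModel):
    t_max: float = Field(20.0, gt=0.0)
    dt: float = Field(0.01, gt=0.0)
    max_level: int = Field(8, ge=1)
    min_mode: int = Field(2, ge=1)


class DilationConfig(BaseModel):
    sequence: list[int] = Field(default_factory=lambda: [3, 2, 3, 1, 3, 2, 3])
    L: float = Field(1.0, gt=0.0)
    g_burst: float = Field(5.0, gt=0.0)
    t_max: float = Field(1.0, gt=0.0)
    dt: float = Field(0.02, gt=0.0)
    width_ratio: float = Field(0.5, gt=0.0, lt=1.0)
    policy: str = "chain"
    fit_factor: float = Field(4.0, gt=0.0)


class RunConfig(BaseModel):
    material: MaterialConfig = MaterialConfig()
    schedule: ScheduleConfig = ScheduleConfig()
    solver: SolverConfig = SolverConfig()
    dilation: DilationConfig = DilationConfig()
    geometry: str = "strip"
    seed: int = 0
    outdir: str = "morphoridge_out"


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a JSON run configuration."""
    text = Path(path).read_text()
    return RunConfig.model_validate(json.loads(text))
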