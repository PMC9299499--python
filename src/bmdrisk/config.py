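"""Analysis configuration: defaults reproduce the framework's standard settings.

CES 50% (the in vivo micronucleus recommendation; 10% is the general
continuous-data default), two-sided 90% profile CI (so the BMDL is the
one-sided 95% lower bound), likelihood-ratio acceptance at p < 0.05, both the
exponential and Hill families, rat body-surface-area scaling and 3-/10-fold
MOE zone thresholds.
"""
from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, field_validator

__all__ = ["AnalysisConfig"]


class AnalysisConfig(BaseModel):
    """Settings echoed verbatim into every report for provenance."""

    ces: float = Field(default=0.50, gt=0, description="critical effect size (fraction over background)")
    ci_level: float = Field(default=0.90, gt=0, lt=1)
    alpha: float = Field(default=0.05, gt=0, lt=1, description="LR acceptance level for covariate parameters")
    families: tuple[str, ...] = ("exponential", "hill")
    covariate_column: str = "covariate_level"
    d_bounds: tuple[float, float] = (0.25, 4.0)
    moe_lower_threshold: float = 3.0
    moe_upper_threshold: float = 10.0
    species: str = "rat"
    dose_units: str = "mg/kg/day"
    response_units: str = "MN-PCE%"
    pod_rule: Literal["min_bmdl"] = "min_bmdl"
    #: nested sub-model ladder stub; only the full 4-parameter models are implemented
    submodel_ladder: Literal["full"] = "full"

    @field_validator("families")
    @classmethod
    def _known_families(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        from .models import FAMILIES

        v = tuple(v)
        bad = set(v) - set(FAMILIES)
        if bad or not v:
            raise ValueError(f"families must be a non-empty subset of {FAMILIES}, got {v}")
        return v

    @field_validator("d_bounds")
    @classmethod
    def _ordered_bounds(cls, v: tuple[float, float]) -> tuple[float, float]:
        lo, hi = v
        if not (0 < lo < hi):
            raise ValueError(f"d_bounds must satisfy 0 < lo < hi, got {v}")
        return (float(lo), float(hi))

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        """Load YAML (or JSON — a YAML subset) and apply keyword overrides."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def echo(self) -> dict:
        return self.model_dump(mode="json")
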