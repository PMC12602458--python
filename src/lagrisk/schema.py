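"""Pipeline configuration schema (validated, unknown keys rejected)."""

from __future__ import annotations

from typing import Dict, List, Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .synthetic import POLLUTANTS


class PipelineConfig(BaseModel):
    """File-level configuration for the end-to-end pipeline."""

    model_config = ConfigDict(extra="forbid")

    exposure_panel: str
    outcome_panel: str
    district_table: Optional[str] = None
    output_dir: str = "lagrisk_out"
    seed: int = 0
    log_level: str = "INFO"

    pollutants: List[str] = Field(default_factory=lambda: list(POLLUTANTS))
    increments: Dict[str, float] = Field(default_factory=dict)
    exposure_basis: Dict[str, dict] = Field(default_factory=dict)
    lag_basis: Dict[str, dict] = Field(default_factory=dict)
    max_lag: int = 7
    outcome: str = "ohca"
    meta_method: str = "reml"

    stratifiers: List[str] = Field(default_factory=list)
    bipollutant_pairs: List[dict] = Field(default_factory=list)
    run_sensitivity: bool = False

    @field_validator("pollutants")
    @classmethod
    def _known_pollutants(cls, v):
        unknown = set(v) - set(POLLUTANTS)
        if unknown:
            raise ValueError(f"unknown pollutants {sorted(unknown)}; expected from {POLLUTANTS}")
        return v

    @field_validator("stratifiers")
    @classmethod
    def _known_stratifiers(cls, v):
        allowed = {"age", "sex", "urbanicity", "season"}
        unknown = set(v) - allowed
        if unknown:
            raise ValueError(f"unknown stratifiers {sorted(unknown)}")
        return v

    @field_validator("meta_method")
    @classmethod
    def _known_method(cls, v):
        if v not in ("reml", "mom", "fixed"):
            raise ValueError("meta_method must be reml, mom or fixed")
        return v
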