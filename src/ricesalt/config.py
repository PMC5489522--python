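"""Run configuration: a versioned, fully serialisable YAML schema.

Every unprinted constant of the model has an explicit default here, so an
emitted provenance block (resolved config + hash) is sufficient to
reproduce any run exactly.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator

from .parameters import TraitParameters, AuxiliaryConstants, HostParameters
from .scenarios import SalinityScenario

SCHEMA_VERSION = 1


class TraitBlock(BaseModel):
    rrbf_min: float = 5.0
    sub_dep_eff: float = 0.62
    sc_max: float = 30.0
    pot_c_seq: float = 0.029
    na_culm_max: float = 26.0
    susc_st: float = 0.00135
    na_to_pan: float = 0.2
    part_cap: float = 0.7
    thresh_l: float = 1.5
    crit_l: float = 35.0

    def build(self) -> TraitParameters:
        return TraitParameters(**self.model_dump())


class AuxBlock(BaseModel):
    sc_min: float = 9.0
    max_na_ext: float = 400.0
    na_leaf_min: float = 0.0
    shape_c: float = 1.0
    na_resp_thresh: float = 0.5
    na_resp_crit: float = 3.0
    bypass_share_rh_lo: float = 58.0
    bypass_share_rh_hi: float = 92.0
    bypass_share_at_lo: float = 35.0
    bypass_share_at_hi: float = 22.0
    bell_centers: tuple[float, float] = (0.8, 1.0)
    bell_sigma: float = 0.05
    k_senescence: float = 1.0
    clamp_sla_stress: bool = True

    def build(self) -> AuxiliaryConstants:
        return AuxiliaryConstants(**self.model_dump())


class HostBlock(BaseModel):
    t_base: float = 8.0
    tt_emergence_anthesis: float = 1200.0
    tt_anthesis_maturity: float = 500.0
    rue: float = 2.2
    k_ext: float = 0.5
    trans_coeff: float = 1.1
    death_rate_maturity: float = 0.03
    n_layers: int = 5
    plant_density: float = 2.0e6

    def build(self) -> HostParameters:
        return HostParameters(**self.model_dump())


class ScenarioBlock(BaseModel):
    pattern: Literal["early_peak", "gradual_ramp", "constant", "custom"] = "constant"
    peak_ec: float = 0.0  # default configuration is an unstressed season
    peak_day_frac: float = 0.15
    release_day_frac: float = 0.33
    decay_days: float = 7.0
    residual_frac: float = 0.05
    plateau_day_frac: float = 0.5
    mm_per_dsm: float = 10.0
    custom_ec: tuple[float, ...] = ()

    def build(self) -> SalinityScenario:
        return SalinityScenario(**self.model_dump())


class EquationModes(BaseModel):
    """Audit switches evaluating the printed equation variants verbatim."""

    literal_rrbf: bool = False
    literal_rpn: bool = False


class SensitivityBlock(BaseModel):
    gamma: float = 500.0
    rel_sd: float = 0.05
    base_n: Optional[int] = None  # None: derived from the sample-size rule
    n_boot: int = 100


class RunConfig(BaseModel):
    schema_version: int = SCHEMA_VERSION
    mode: Literal["field", "hydroponic"] = "field"
    seed: int = 0
    season_length: int = 150
    hydroponic_treatment_mm: float = 0.0
    # optional external forcing files (tab-delimited); when unset, the
    # synthetic generators provide the season
    weather_file: Optional[str] = None
    salinity_file: Optional[str] = None
    traits: TraitBlock = Field(default_factory=TraitBlock)
    aux: AuxBlock = Field(default_factory=AuxBlock)
    host: HostBlock = Field(default_factory=HostBlock)
    scenario: ScenarioBlock = Field(default_factory=ScenarioBlock)
    equation_modes: EquationModes = Field(default_factory=EquationModes)
    sensitivity: SensitivityBlock = Field(default_factory=SensitivityBlock)

    @field_validator("season_length")
    @classmethod
    def _positive_season(cls, v: int) -> int:
        if v <= 0:
            raise ValueError("season_length must be positive")
        return v

    # ------------------------------------------------------------ I/O
    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)

    def resolved_dict(self) -> dict:
        return self.model_dump(mode="json")

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.resolved_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def provenance(self) -> dict:
        """Resolved defaults plus the config hash; reproduces the run exactly."""
        return {"config": self.resolved_dict(), "sha256": self.config_hash()}
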