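"""Run configuration: schema-validated parameter sets with explicit units.

Keys carry unit suffixes (``p_s_mmHg``, ``D_mm``, ``E_Pa``, ...); unknown
keys are rejected so a typo cannot silently fall back to a default. The
effective configuration is echoed into every result for reproducibility.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import ConfigurationError
from .types import BloodProperties, PressureState, VesselGeometry, WallMaterial
from .units import mm

__all__ = ["RunConfig", "load_config", "config_from_dict"]


class RunConfig(BaseModel):
    """Validated parameter set for a single flow/SEDI computation."""

    model_config = ConfigDict(extra="forbid")

    p_s_mmHg: float = Field(gt=0, description="systolic pressure [mmHg]")
    p_d_mmHg: float = Field(gt=0, description="diastolic pressure [mmHg]")
    D_mm: float = Field(gt=0, description="reference outer diameter [mm]")
    h_mm: float = Field(gt=0, description="reference wall thickness [mm]")
    E_Pa: float = Field(gt=0, description="circumferential elastic modulus [Pa]")
    phi: float = Field(gt=0, le=1, description="expansion constraint coefficient")
    mode: Literal["fixed_beta", "fixed_Re", "self_consistent"] = "fixed_beta"
    beta: Optional[float] = None
    Re: Optional[float] = Field(default=None, gt=0)
    area_strain: Optional[float] = Field(
        default=None, ge=0,
        description="diastole→systole lumen area strain deriving D_s, h_s",
    )
    n_per_min: Optional[float] = Field(default=None, gt=0)
    mu_Pa_s: float = Field(default=4.0e-3, gt=0)
    rho_kg_m3: float = Field(default=1050.0, gt=0)
    gamma_convention: Optional[Literal["kgf", "si"]] = None
    seed: int = 0

    @model_validator(mode="after")
    def _mode_inputs(self) -> "RunConfig":
        if self.p_s_mmHg <= self.p_d_mmHg:
            raise ValueError("p_s_mmHg must exceed p_d_mmHg")
        if self.mode == "fixed_beta" and self.beta is None:
            raise ValueError("mode=fixed_beta requires key 'beta'")
        if self.mode == "fixed_Re" and self.Re is None:
            raise ValueError("mode=fixed_Re requires key 'Re'")
        return self

    def pressure(self) -> PressureState:
        return PressureState.from_mmhg(self.p_s_mmHg, self.p_d_mmHg)

    def geometry(self) -> VesselGeometry:
        if self.area_strain is not None:
            return VesselGeometry.from_area_strain(
                mm(self.D_mm), mm(self.h_mm), self.area_strain
            )
        return VesselGeometry.from_mm(self.D_mm, self.h_mm)

    def material(self) -> WallMaterial:
        return WallMaterial(E=self.E_Pa, phi=self.phi)

    def blood(self, default_convention: str = "kgf") -> BloodProperties:
        return BloodProperties(
            rho=self.rho_kg_m3,
            mu=self.mu_Pa_s,
            gamma_convention=self.gamma_convention or default_convention,
        )


def config_from_dict(raw: dict, source: str = "<dict>") -> RunConfig:
    """Validate a raw mapping, naming the offending field on failure."""
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in err['loc']) or '<root>'}: {err['msg']}"
            for err in exc.errors()
        )
        raise ConfigurationError(f"invalid config {source}: {details}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON or YAML configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    text = path.read_text()
    try:
        if path.suffix.lower() in (".yaml", ".yml"):
            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    return config_from_dict(raw, source=str(path))
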