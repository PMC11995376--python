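"""Run configuration: a validated YAML parameter file.

All parameters default to the 25 C lactose-water set, so an empty file is a
complete, runnable configuration.  Unknown keys are rejected and bound
violations name the offending key.
"""

from __future__ import annotations

import hashlib
import math
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .composition import Species, SpeciesRegistry
from .dissolution import SimulationParams
from .equilibria import SolubilityModel
from .exceptions import ConfigError
from .fixtures import FixtureSpec
from .thermo import MargulesModel, MutarotationModel

__all__ = ["RunConfig", "load_config", "config_hash"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ThermodynamicsConfig(_Section):
    A: float = -5.8
    K_star: float = Field(1.60, gt=0)
    slope: float = Field(0.0, ge=0)
    k_alpha: float = Field(0.64, ge=0)  # 1/h


class SolubilityConfig(_Section):
    K_sp: float = Field(0.00494, gt=0)


class CrystalsConfig(_Section):
    rho_c: float = Field(1545.0, gt=0)  # kg/m^3
    k_v: float = Field(math.pi / 6.0, gt=0)
    seed_mean_um: float = Field(10.0, gt=0)
    seed_sd_um: float = Field(1.0, ge=0)
    n_characteristics: int = Field(200, ge=1)


class SimulationConfig(_Section):
    loading: float = Field(0.25, ge=0)  # g powder / g water
    water_mass_g: float = Field(50.0, gt=0)
    horizon_h: float = Field(24.0, gt=0)
    k_D: float = Field(1e-3, gt=0)  # m/s
    rtol: float = Field(1e-10, gt=0)
    atol: float = Field(1e-15, gt=0)


class SpeciesConfig(_Section):
    name: str
    molar_mass: float = Field(gt=0)
    role: str = "foreign_sugar"


class FixturesConfig(_Section):
    A_true: float = -5.8
    K_star_true: float = Field(1.60, gt=0)
    slope_true: float = Field(1.5, ge=0)
    n_activity: int = Field(20, ge=2)
    n_ratio: int = Field(15, ge=2)
    xw_min: float = Field(0.96, gt=0.9)
    xw_max: float = Field(0.999, le=1.0)
    sd_aw: float = Field(5e-4, ge=0)
    sd_kx: float = Field(0.01, ge=0)


class CalibrationReport(_Section):
    """Standard errors emitted by `anomer calibrate` (informational)."""

    se_A: Optional[float] = None
    se_K_star: Optional[float] = None
    se_slope: Optional[float] = None
    n_activity: Optional[int] = None
    n_ratio: Optional[int] = None


class RunConfig(_Section):
    thermodynamics: ThermodynamicsConfig = Field(default_factory=ThermodynamicsConfig)
    solubility: SolubilityConfig = Field(default_factory=SolubilityConfig)
    crystals: CrystalsConfig = Field(default_factory=CrystalsConfig)
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    species: list[SpeciesConfig] = Field(default_factory=list)
    fixtures: FixturesConfig = Field(default_factory=FixturesConfig)
    seed: int = 0
    verbosity: str = "info"
    #: optional informational section written by `anomer calibrate`
    calibration: Optional[CalibrationReport] = None

    # -- factories for the domain objects -----------------------------------

    def registry(self) -> SpeciesRegistry:
        extra = [
            Species(sp.name, sp.molar_mass, sp.role) for sp in self.species
        ]
        reg = SpeciesRegistry.default()
        return reg.with_species(*extra) if extra else reg

    def margules_model(self) -> MargulesModel:
        return MargulesModel(A=self.thermodynamics.A)

    def mutarotation_model(self) -> MutarotationModel:
        t = self.thermodynamics
        return MutarotationModel(K_star=t.K_star, slope=t.slope, k_alpha=t.k_alpha)

    def solubility_model(self) -> SolubilityModel:
        return SolubilityModel(
            K_sp=self.solubility.K_sp,
            margules=self.margules_model(),
            mutarotation=self.mutarotation_model(),
            registry=self.registry(),
        )

    def simulation_params(self) -> SimulationParams:
        c, s = self.crystals, self.simulation
        return SimulationParams(
            solubility=self.solubility_model(),
            rho_c=c.rho_c,
            k_v=c.k_v,
            k_D=s.k_D,
            loading=s.loading,
            water_mass_g=s.water_mass_g,
            seed_mean=c.seed_mean_um * 1e-6,
            seed_sd=c.seed_sd_um * 1e-6,
            n_characteristics=c.n_characteristics,
            horizon_h=s.horizon_h,
            rtol=s.rtol,
            atol=s.atol,
        )

    def fixture_spec(self, seed: int | None = None) -> FixtureSpec:
        f = self.fixtures
        return FixtureSpec(
            A_true=f.A_true,
            K_star_true=f.K_star_true,
            slope_true=f.slope_true,
            activity_grid=np.linspace(f.xw_min, f.xw_max, f.n_activity),
            ratio_grid=np.linspace(f.xw_min, f.xw_max, f.n_ratio),
            sd_aw=f.sd_aw,
            sd_kx=f.sd_kx,
            seed=self.seed if seed is None else seed,
        )


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; an empty file yields all defaults."""
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    try:
        raw = yaml.safe_load(p.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {p}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(loc) for loc in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        )
        raise ConfigError(f"invalid config {p}: {details}") from exc


def config_hash(config: RunConfig) -> str:
    """Stable SHA-256 over the normalised config (for run logging)."""
    blob = config.model_dump_json().encode()
    return hashlib.sha256(blob).hexdigest()[:16]
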