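"""YAML run configuration, schema-validated with pydantic.

One file describes a field: site geometry, soil, the staged crop profile,
the Warabandi turn calendar, channel flow/area, the synthetic-weather
season (used when no weather file is given) and scheduler options. Every
default mirrors the package defaults; ``example_config`` emits a complete,
commented starting point.
"""

from __future__ import annotations

from datetime import date as Date
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .crop import CropProfile, CropStage
from .met import SiteGeometry
from .scheduler import FlowSpec, WarabandiCalendar
from .soil import SoilProfile
from .synth import SeasonSpec

__all__ = ["RunConfig", "load_config", "example_config"]


class SiteSection(BaseModel):
    latitude: float = 24.9
    longitude: float = 67.1
    elevation_z: float = 20.0
    anemometer_height: float = 10.0


class SoilSection(BaseModel):
    theta_fc: float = 0.32
    theta_wp: float = 0.12


class StageSection(BaseModel):
    name: str
    length_days: int
    kc: float


class CropSection(BaseModel):
    crop_name: str = "lemon"
    planting_date: Date = Date(2018, 2, 1)
    effective_root_depth: float = 1.1
    depletion_fraction_p: float = Field(default=0.5, gt=0.0, lt=1.0)
    stages: list[StageSection] = Field(
        default_factory=lambda: [
            StageSection(name="initial", length_days=60, kc=0.65),
            StageSection(name="development", length_days=60, kc=0.75),
            StageSection(name="mid", length_days=90, kc=0.75),
            StageSection(name="late", length_days=60, kc=0.70),
        ]
    )


class CalendarSection(BaseModel):
    turn_anchor: Date = Date(2018, 2, 2)  # a Friday
    period_days: int = Field(default=7, ge=1)
    explicit_turns: list[Date] | None = None


class FlowSection(BaseModel):
    flow_rate: float = Field(default=400.0, gt=0.0)  # L/min
    field_area: float = Field(default=8093.71, gt=0.0)  # m2 (2 acres)


class SeasonSection(BaseModel):
    start_date: Date = Date(2018, 2, 1)
    n_days: int = Field(default=270, ge=1)
    t_mean_annual: float = 31.0
    t_amplitude: float = 12.5
    diurnal_range: float = 14.0
    rh_base: float = 55.0
    wind_mean: float = 4.0
    noise_sd_t: float = 1.0
    noise_sd_rh: float = 8.0
    noise_sd_wind: float = 0.8
    random_seed: int = 0


class OptionsSection(BaseModel):
    ea_pairing: str = "fao"
    k_rs: float = Field(default=0.16, gt=0.0)
    initial_depletion_mm: float = Field(default=0.0, ge=0.0)
    forecast: str = "persistence"
    forecast_window_k: int = Field(default=3, ge=1)
    raw_etc_adjust: bool = False

    @field_validator("ea_pairing")
    @classmethod
    def _check_pairing(cls, v: str) -> str:
        if v not in ("fao", "literal"):
            raise ValueError("ea_pairing must be 'fao' or 'literal'")
        return v

    @field_validator("forecast")
    @classmethod
    def _check_forecast(cls, v: str) -> str:
        if v not in ("persistence", "perfect"):
            raise ValueError("forecast must be 'persistence' or 'perfect'")
        return v


class RunConfig(BaseModel):
    site: SiteSection = Field(default_factory=SiteSection)
    soil: SoilSection = Field(default_factory=SoilSection)
    crop: CropSection = Field(default_factory=CropSection)
    calendar: CalendarSection = Field(default_factory=CalendarSection)
    flow: FlowSection = Field(default_factory=FlowSection)
    season: SeasonSection = Field(default_factory=SeasonSection)
    options: OptionsSection = Field(default_factory=OptionsSection)

    # -- adapters to the domain objects ------------------------------------
    def site_geometry(self) -> SiteGeometry:
        return SiteGeometry(**self.site.model_dump())

    def soil_profile(self) -> SoilProfile:
        return SoilProfile(**self.soil.model_dump())

    def crop_profile(self) -> CropProfile:
        return CropProfile(
            crop_name=self.crop.crop_name,
            planting_date=self.crop.planting_date,
            stages=tuple(
                CropStage(s.name, s.length_days, s.kc) for s in self.crop.stages
            ),
            effective_root_depth=self.crop.effective_root_depth,
            depletion_fraction_p=self.crop.depletion_fraction_p,
        )

    def warabandi_calendar(self) -> WarabandiCalendar:
        turns = self.calendar.explicit_turns
        return WarabandiCalendar(
            turn_anchor=self.calendar.turn_anchor,
            period_days=self.calendar.period_days,
            explicit_turns=tuple(turns) if turns else None,
        )

    def flow_spec(self) -> FlowSpec:
        return FlowSpec(**self.flow.model_dump())

    def season_spec(self) -> SeasonSpec:
        return SeasonSpec(**self.season.model_dump())


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML config; None gives the built-in defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        raise ValueError(f"malformed config {path}: {exc}") from exc
    return RunConfig.model_validate(data)


def example_config() -> str:
    """A complete config.example with every default spelled out."""
    cfg = RunConfig()
    data = cfg.model_dump(mode="json")
    header = (
        "# irrisched run configuration (all values shown are the defaults)\n"
        "# site: station location; anemometer_height is the wind measurement\n"
        "#   height above ground (10 m for third-party wind products)\n"
        "# soil: volumetric water content at field capacity / wilting point\n"
        "# crop: staged Kc curve; kc is the value reached at the stage end\n"
        "# calendar: weekly Warabandi turns anchored on a known turn day\n"
        "# flow: channel flow rate (L/min) and irrigated area (m2; 2 acres)\n"
        "# season: synthetic-weather generator (hot semi-arid preset)\n"
        "# options: ea_pairing fao|literal; forecast persistence|perfect\n"
    )
    return header + yaml.safe_dump(data, sort_keys=False)
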