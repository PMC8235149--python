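"""Seeded synthetic seasons: daily weather, hourly sensor traces, fixtures.

The generator emulates a hot semi-arid (Karachi-like) growing season: a
sinusoidal annual temperature cycle peaking in mid-June, a fixed diurnal
range split symmetrically around the daily mean, bounded Gaussian noise per
channel, and summer daily maxima reaching the low 50s degC under the
bundled preset. Soil-moisture sensing is emulated at the hourly cadence of
a field telemetry node: volumetric water content decays with the day's
crop evapotranspiration and jumps toward field capacity when irrigation is
applied, so a noise-free trace reproduces the bookkeeping depletion
exactly.

``trial_irrigation_log`` packages the published 17-event irrigation log of the
two 2-acre trial areas (traditional vs demand-scheduled) for the
comparison reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date as Date, datetime, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .met import DailyWeather
from .soil import SoilProfile

__all__ = [
    "SeasonSpec",
    "karachi_season",
    "generate_weather_season",
    "SensorTrace",
    "simulate_sensor",
    "DailySample",
    "hourly_to_daily",
    "trial_irrigation_log",
    "weather_to_frame",
    "frame_to_weather",
]

#: Day of year of the warmest day in the sinusoidal cycle (mid June).
PEAK_DOY = 166


@dataclass(frozen=True)
class SeasonSpec:
    """Parameters of one synthetic season.

    Temperatures follow t_mean_annual + t_amplitude * cos(2 pi (doy -
    peak)/365.25) with the diurnal range split evenly around the daily
    mean; each channel gets independent Gaussian noise with the given
    standard deviation. A single seed drives every stochastic channel.
    """

    start_date: Date
    n_days: int
    t_mean_annual: float = 25.0
    t_amplitude: float = 10.0
    diurnal_range: float = 12.0
    rh_base: float = 55.0
    wind_mean: float = 3.0
    noise_sd_t: float = 1.5
    noise_sd_rh: float = 6.0
    noise_sd_wind: float = 0.8
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError(f"n_days must be >= 1, got {self.n_days}")
        if self.diurnal_range < 0 or self.t_amplitude < 0:
            raise ValueError("diurnal_range and t_amplitude must be >= 0")


def karachi_season(
    start_date: Date = Date(2018, 2, 1), n_days: int = 270, seed: int = 0
) -> SeasonSpec:
    """Preset for the Gadap (Karachi) trial regime: a February-October season
    whose summer daily maxima reach the low 50s degC, humid sea-breeze RH
    and moderate winds."""
    return SeasonSpec(
        start_date=start_date,
        n_days=n_days,
        t_mean_annual=31.0,
        t_amplitude=12.5,
        diurnal_range=14.0,
        rh_base=55.0,
        wind_mean=4.0,
        noise_sd_t=1.0,
        noise_sd_rh=8.0,
        noise_sd_wind=0.8,
        random_seed=seed,
    )


def generate_weather_season(spec: SeasonSpec) -> list[DailyWeather]:
    """Deterministic (given seed) list of daily weather records."""
    rng = np.random.default_rng(spec.random_seed)
    days = [spec.start_date + timedelta(days=i) for i in range(spec.n_days)]
    doy = np.array([d.timetuple().tm_yday for d in days], dtype=float)
    t_mean = spec.t_mean_annual + spec.t_amplitude * np.cos(
        2.0 * np.pi * (doy - PEAK_DOY) / 365.25
    )
    half = 0.5 * spec.diurnal_range
    t_max = t_mean + half + rng.normal(0.0, spec.noise_sd_t, spec.n_days)
    t_min = t_mean - half + rng.normal(0.0, spec.noise_sd_t, spec.n_days)
    t_min = np.minimum(t_min, t_max)  # noise must not invert the extremes
    rh_max = np.clip(spec.rh_base + 20.0 + rng.normal(0.0, spec.noise_sd_rh, spec.n_days), 5.0, 100.0)
    rh_min = np.clip(spec.rh_base - 15.0 + rng.normal(0.0, spec.noise_sd_rh, spec.n_days), 2.0, 100.0)
    rh_min = np.minimum(rh_min, rh_max)
    wind = np.maximum(0.0, spec.wind_mean + rng.normal(0.0, spec.noise_sd_wind, spec.n_days))
    return [
        DailyWeather(
            date=d,
            t_max=float(t_max[i]),
            t_min=float(t_min[i]),
            rh_max=float(rh_max[i]),
            rh_min=float(rh_min[i]),
            wind_speed=float(wind[i]),
        )
        for i, d in enumerate(days)
    ]


@dataclass
class SensorTrace:
    """Hourly telemetry: timestamps plus theta (m3/m3), t_air (degC), rh (%)."""

    timestamps: list[datetime]
    theta: np.ndarray
    t_air: np.ndarray
    rh: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.timestamps)
        if not (len(self.theta) == len(self.t_air) == len(self.rh) == n):
            raise ValueError("all sensor channels must share one timestamp axis")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": [t.isoformat() for t in self.timestamps],
                "theta": self.theta,
                "t_air": self.t_air,
                "rh": self.rh,
            }
        )


def simulate_sensor(
    weather: Sequence[DailyWeather],
    soil: SoilProfile,
    root_depth: float,
    etc_series: Sequence[float],
    irrigation: Mapping[Date, float] | None = None,
    seed: int = 0,
    theta_noise_sd: float = 0.0,
) -> SensorTrace:
    """Hourly soil-moisture/temperature/humidity trace for a run of days.

    theta starts at field capacity and loses the day's ETc spread evenly
    over 24 hours; irrigation depths (mm, keyed by date) are added after
    the final hour of their day, so each day's last reading is the
    end-of-day state — a noise-free trace round-trips exactly to the
    bookkeeping depletion. Air channels interpolate the daily extremes
    with a diurnal sinusoid (coolest 05:00, warmest 17:00).
    """
    if len(etc_series) != len(weather):
        raise ValueError(
            f"etc_series length {len(etc_series)} != weather length {len(weather)}"
        )
    irrigation = dict(irrigation or {})
    for d in irrigation:
        if not weather[0].date <= d <= weather[-1].date:
            raise ValueError(f"irrigation date {d} outside the weather range")
    rng = np.random.default_rng(seed)
    hours = np.arange(1, 25, dtype=float)  # reading at the end of each hour
    diurnal = 0.5 - 0.5 * np.cos(2.0 * np.pi * (hours - 5.0) / 24.0)

    timestamps: list[datetime] = []
    theta_all: list[np.ndarray] = []
    t_all: list[np.ndarray] = []
    rh_all: list[np.ndarray] = []
    theta = soil.theta_fc
    theta_floor = 0.8 * soil.theta_wp  # sensors bottom out near wilting
    for w, etc in zip(weather, etc_series):
        step = etc / (1000.0 * root_depth) / 24.0
        day_theta = theta - step * hours
        theta = float(day_theta[-1])
        if w.date in irrigation:
            theta = min(soil.theta_fc, theta + irrigation[w.date] / (1000.0 * root_depth))
            day_theta = day_theta.copy()
            day_theta[-1] = theta
        day_theta = np.clip(day_theta, theta_floor, soil.theta_fc)
        theta = float(np.clip(theta, theta_floor, soil.theta_fc))
        if theta_noise_sd > 0.0:
            day_theta = np.clip(
                day_theta + rng.normal(0.0, theta_noise_sd, 24),
                theta_floor,
                soil.theta_fc,
            )
        timestamps.extend(
            datetime(w.date.year, w.date.month, w.date.day, 0, 0) + timedelta(hours=float(h))
            for h in hours
        )
        theta_all.append(day_theta)
        t_all.append(w.t_min + (w.t_max - w.t_min) * diurnal)
        rh_all.append(w.rh_max - (w.rh_max - w.rh_min) * diurnal)

    return SensorTrace(
        timestamps=timestamps,
        theta=np.concatenate(theta_all),
        t_air=np.concatenate(t_all),
        rh=np.concatenate(rh_all),
    )


@dataclass(frozen=True)
class DailySample:
    """One day aggregated from hourly telemetry: weather extremes + mean theta."""

    weather: DailyWeather
    theta_mean: float
    theta_last: float


def hourly_to_daily(trace: SensorTrace, wind_speed: float = 0.0) -> list[DailySample]:
    """Aggregate an hourly trace to daily records.

    Temperature and RH become the day's extrema, theta the arithmetic mean
    of the 24 readings (theta_last keeps the end-of-day reading for exact
    bookkeeping comparisons). Days with fewer than 24 readings are skipped
    with a warning. The trace has no wind channel; `wind_speed` fills it.
    """
    by_day: dict[Date, list[int]] = {}
    for i, ts in enumerate(trace.timestamps):
        # the final reading of a day is stamped at midnight of the next day
        d = (ts - timedelta(seconds=1)).date()
        by_day.setdefault(d, []).append(i)
    out = []
    for d in sorted(by_day):
        idx = by_day[d]
        if len(idx) != 24:
            warnings.warn(f"skipping partial day {d}: {len(idx)}/24 readings", stacklevel=2)
            continue
        t = trace.t_air[idx]
        rh = trace.rh[idx]
        th = trace.theta[idx]
        out.append(
            DailySample(
                weather=DailyWeather(
                    date=d,
                    t_max=float(t.max()),
                    t_min=float(t.min()),
                    rh_max=float(rh.max()),
                    rh_min=float(rh.min()),
                    wind_speed=wind_speed,
                ),
                theta_mean=float(th.mean()),
                theta_last=float(th[-1]),
            )
        )
    return out


# (day-of-year, Area A litres, Area B litres) — published 17-event log of
# the two-acre trial: Area A traditional, Area B demand-scheduled.
_TRIAL_EVENT_ROWS = (
    (32, 7110, 6266),
    (67, 5273, 0),
    (78, 6588, 4799),
    (89, 5212, 0),
    (105, 4873, 6399),
    (115, 5553, 0),
    (131, 5452, 5120),
    (159, 7117, 0),
    (169, 5277, 3922),
    (179, 4224, 0),
    (192, 5833, 3924),
    (210, 6563, 7546),
    (220, 4624, 0),
    (226, 7856, 0),
    (260, 5104, 0),
    (291, 4316, 7242),
    (304, 5894, 0),
)


def trial_irrigation_log() -> pd.DataFrame:
    """The published per-event irrigation log of both trial areas.

    Columns: day_of_year, area_a_l (traditional), area_b_l
    (demand-scheduled); zero means the scheduled system skipped that event.
    """
    return pd.DataFrame(_TRIAL_EVENT_ROWS, columns=["day_of_year", "area_a_l", "area_b_l"])


# ---------------------------------------------------------------------------
# Delimited-text round trip for weather tables

WEATHER_COLUMNS = ["date", "t_max", "t_min", "rh_max", "rh_min", "wind_speed"]


def weather_to_frame(weather: Sequence[DailyWeather]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "date": [w.date.isoformat() for w in weather],
            "t_max": [w.t_max for w in weather],
            "t_min": [w.t_min for w in weather],
            "rh_max": [w.rh_max for w in weather],
            "rh_min": [w.rh_min for w in weather],
            "wind_speed": [w.wind_speed for w in weather],
        }
    )


def frame_to_weather(frame: pd.DataFrame) -> list[DailyWeather]:
    missing = [c for c in WEATHER_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"weather table missing columns: {missing}")
    return [
        DailyWeather(
            date=Date.fromisoformat(str(row.date)),
            t_max=float(row.t_max),
            t_min=float(row.t_min),
            rh_max=float(row.rh_max),
            rh_min=float(row.rh_min),
            wind_speed=float(row.wind_speed),
        )
        for row in frame.itertuples(index=False)
    ]
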