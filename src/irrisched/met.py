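"""Daily grass reference evapotranspiration (FAO-56 Penman-Monteith).

Implements the full daily ET0 chain for sites where only air temperature,
relative humidity and wind speed are measured: saturation/actual vapour
pressure, the vapour-pressure-curve slope, atmospheric pressure and the
psychrometric constant, logarithmic wind-profile adjustment to 2 m, and a
temperature-range (Hargreaves-type) estimate of solar and net radiation
from extraterrestrial radiation. Soil heat flux G is taken as zero at the
daily time step.

Two published conventions exist for combining the RH extremes into the
actual vapour pressure e_a; the FAO-56 pairing e0(Tmin)*RHmax + e0(Tmax)*RHmin
is the default because it guarantees e_a <= e_s, and the alternative
("literal") pairing e0(Tmax)*RHmax + e0(Tmin)*RHmin is available through the
``ea_pairing`` argument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date as Date

__all__ = [
    "SiteGeometry",
    "DailyWeather",
    "AtmosphericTerms",
    "saturation_vapor_pressure",
    "mean_saturation_vapor_pressure",
    "actual_vapor_pressure",
    "actual_vapor_pressure_from_mean_rh",
    "vapor_pressure_slope",
    "atmospheric_pressure",
    "psychrometric_constant",
    "wind_to_2m",
    "extraterrestrial_radiation",
    "net_radiation",
    "reference_et0",
]

#: Solar constant, MJ m-2 min-1.
SOLAR_CONSTANT = 0.0820
#: Stefan-Boltzmann constant, MJ K-4 m-2 day-1.
STEFAN_BOLTZMANN = 4.903e-9
#: Albedo of the hypothetical grass reference surface.
GRASS_ALBEDO = 0.23
#: Default solar-radiation adjustment coefficient for interior locations,
#: degC^-0.5 (coastal locations would use 0.19).
KRS_INTERIOR = 0.16
#: Lowest land-surface elevation on Earth, m (Dead Sea shore).
MIN_ELEVATION_M = -430.0
#: Minimum anemometer height for which the log wind profile gives a positive
#: adjustment (ln argument must exceed 1), m.
MIN_ANEMOMETER_HEIGHT_M = (1.0 + 5.42) / 67.8


@dataclass(frozen=True)
class SiteGeometry:
    """Where the station sits and how its anemometer is mounted.

    Parameters
    ----------
    latitude : float
        Decimal degrees, positive north.
    longitude : float
        Decimal degrees; informational only (daily radiation needs latitude).
    elevation_z : float
        Metres above sea level; sets atmospheric pressure and clear-sky
        radiation.
    anemometer_height : float
        Height of the wind measurement above ground, m. Third-party wind
        products are typically at 10 m; agrometeorological masts at 2-3 m.
    """

    latitude: float
    longitude: float = 0.0
    elevation_z: float = 0.0
    anemometer_height: float = 10.0

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude must be in [-90, 90], got {self.latitude}")
        if self.elevation_z < MIN_ELEVATION_M:
            raise ValueError(f"elevation_z must be >= {MIN_ELEVATION_M} m")
        if self.anemometer_height <= MIN_ANEMOMETER_HEIGHT_M:
            raise ValueError(
                "anemometer_height must exceed "
                f"{MIN_ANEMOMETER_HEIGHT_M:.3f} m, got {self.anemometer_height}"
            )


@dataclass(frozen=True)
class DailyWeather:
    """One day's temperature/humidity/wind observation.

    Wind speed is at the site's anemometer height, not necessarily 2 m.
    """

    date: Date
    t_max: float
    t_min: float
    rh_max: float
    rh_min: float
    wind_speed: float

    def __post_init__(self) -> None:
        for name in ("t_max", "t_min", "rh_max", "rh_min", "wind_speed"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.t_max < self.t_min:
            raise ValueError(f"t_max ({self.t_max}) < t_min ({self.t_min})")
        if not (0.0 <= self.rh_min <= 100.0 and 0.0 <= self.rh_max <= 100.0):
            raise ValueError("relative humidity must be in [0, 100] %")
        if self.rh_max < self.rh_min:
            raise ValueError(f"rh_max ({self.rh_max}) < rh_min ({self.rh_min})")
        if self.wind_speed < 0.0:
            raise ValueError("wind_speed must be >= 0")

    @property
    def t_mean(self) -> float:
        """Daily mean air temperature, (t_max + t_min) / 2, degC."""
        return 0.5 * (self.t_max + self.t_min)


@dataclass(frozen=True)
class AtmosphericTerms:
    """Every sub-term of the daily Penman-Monteith evaluation.

    Units: vapour pressures kPa; delta and gamma kPa/degC; pressure kPa;
    u2 m/s; radiation terms MJ m-2 day-1; et0 mm/day. G is identically zero
    at the daily time step.
    """

    e0_tmax: float
    e0_tmin: float
    e_s: float
    e_a: float
    delta: float
    pressure_P: float
    gamma: float
    u2: float
    R_a: float
    R_s: float
    R_so: float
    R_ns: float
    R_nl: float
    R_n: float
    G: float
    et0: float


def _require_finite(x: float, name: str) -> None:
    if not math.isfinite(x):
        raise ValueError(f"{name} must be finite, got {x}")


def saturation_vapor_pressure(t: float) -> float:
    """Saturation vapour pressure e0(T) at air temperature `t` (degC), kPa.

    e0(T) = 0.6108 * exp(17.27 T / (T + 237.3)); strictly increasing in T.
    """
    _require_finite(t, "t")
    if t <= -237.3:
        raise ValueError(f"temperature must exceed -237.3 degC, got {t}")
    return 0.6108 * math.exp(17.27 * t / (t + 237.3))


def mean_saturation_vapor_pressure(t_max: float, t_min: float) -> float:
    """Daily mean saturation vapour pressure e_s = [e0(Tmax) + e0(Tmin)] / 2, kPa.

    Because e0(T) is convex, evaluating at the daily extremes and averaging
    is preferred over e0(Tmean), which underestimates e_s.
    """
    if t_max < t_min:
        raise ValueError(f"t_max ({t_max}) < t_min ({t_min})")
    return 0.5 * (saturation_vapor_pressure(t_max) + saturation_vapor_pressure(t_min))


def actual_vapor_pressure(
    t_max: float,
    t_min: float,
    rh_max: float,
    rh_min: float,
    pairing: str = "fao",
) -> float:
    """Actual vapour pressure e_a from RH extremes, kPa.

    ``pairing="fao"`` (default) pairs the night-time extreme RHmax with Tmin
    and the afternoon extreme RHmin with Tmax:

        e_a = [e0(Tmin) RHmax/100 + e0(Tmax) RHmin/100] / 2,

    which guarantees e_a <= e_s. ``pairing="literal"`` pairs like with like
    (e0(Tmax) RHmax, e0(Tmin) RHmin) instead.
    """
    for v, name in ((rh_max, "rh_max"), (rh_min, "rh_min")):
        _require_finite(v, name)
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} must be in [0, 100] %, got {v}")
    e_tmax = saturation_vapor_pressure(t_max)
    e_tmin = saturation_vapor_pressure(t_min)
    if pairing == "fao":
        return 0.5 * (e_tmin * rh_max / 100.0 + e_tmax * rh_min / 100.0)
    if pairing == "literal":
        return 0.5 * (e_tmax * rh_max / 100.0 + e_tmin * rh_min / 100.0)
    raise ValueError(f"unknown e_a pairing {pairing!r} (expected 'fao' or 'literal')")


def actual_vapor_pressure_from_mean_rh(t_max: float, t_min: float, rh_mean: float) -> float:
    """Fallback e_a = RHmean/100 * e_s for stations reporting only mean RH, kPa."""
    _require_finite(rh_mean, "rh_mean")
    if not 0.0 <= rh_mean <= 100.0:
        raise ValueError(f"rh_mean must be in [0, 100] %, got {rh_mean}")
    return rh_mean / 100.0 * mean_saturation_vapor_pressure(t_max, t_min)


def vapor_pressure_slope(t: float) -> float:
    """Slope of the saturation-vapour-pressure curve at `t` (degC), kPa/degC.

    Delta = 4098 e0(T) / (T + 237.3)^2, evaluated at the daily mean
    temperature in the Penman-Monteith equation.
    """
    return 4098.0 * saturation_vapor_pressure(t) / (t + 237.3) ** 2


def atmospheric_pressure(elevation_z: float) -> float:
    """Mean atmospheric pressure at elevation `elevation_z` (m), kPa.

    P = 101.3 * ((293 - 0.0065 z) / 293)^5.26 — a standard-atmosphere
    profile anchored at 101.3 kPa at sea level.
    """
    _require_finite(elevation_z, "elevation_z")
    if elevation_z < MIN_ELEVATION_M:
        raise ValueError(f"elevation_z must be >= {MIN_ELEVATION_M} m, got {elevation_z}")
    return 101.3 * ((293.0 - 0.0065 * elevation_z) / 293.0) ** 5.26


def psychrometric_constant(pressure_P: float) -> float:
    """Psychrometric constant gamma = 0.665e-3 * P, kPa/degC, with P in kPa."""
    _require_finite(pressure_P, "pressure_P")
    if pressure_P <= 0.0:
        raise ValueError(f"pressure_P must be > 0, got {pressure_P}")
    return 0.665e-3 * pressure_P


def wind_to_2m(u_z: float, measurement_height: float) -> float:
    """Adjust wind speed measured at `measurement_height` (m) to 2 m, m/s.

    u2 = u_z * 4.87 / ln(67.8 z - 5.42), the logarithmic profile over a
    short grass surface. z is the height of the measurement above ground
    (10 m for typical synoptic/third-party wind data).
    """
    _require_finite(u_z, "u_z")
    if u_z < 0.0:
        raise ValueError(f"u_z must be >= 0, got {u_z}")
    if measurement_height <= MIN_ANEMOMETER_HEIGHT_M:
        raise ValueError(
            f"measurement_height must exceed {MIN_ANEMOMETER_HEIGHT_M:.3f} m, "
            f"got {measurement_height}"
        )
    return u_z * 4.87 / math.log(67.8 * measurement_height - 5.42)


def extraterrestrial_radiation(latitude: float, day_of_year: int) -> float:
    """Daily extraterrestrial radiation R_a, MJ m-2 day-1.

    Standard solar geometry: inverse relative Earth-Sun distance, solar
    declination and sunset hour angle, with the sunset-angle cosine clamped
    to [-1, 1] so polar night returns 0 and polar day a full 24 h arc.
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude must be in [-90, 90], got {latitude}")
    if not 1 <= day_of_year <= 366:
        raise ValueError(f"day_of_year must be in [1, 366], got {day_of_year}")
    phi = math.radians(latitude)
    j = 2.0 * math.pi * day_of_year / 365.0
    dr = 1.0 + 0.033 * math.cos(j)
    delta = 0.409 * math.sin(j - 1.39)
    cos_ws = -math.tan(phi) * math.tan(delta)
    ws = math.acos(min(1.0, max(-1.0, cos_ws)))
    ra = (24.0 * 60.0 / math.pi) * SOLAR_CONSTANT * dr * (
        ws * math.sin(phi) * math.sin(delta)
        + math.cos(phi) * math.cos(delta) * math.sin(ws)
    )
    return max(ra, 0.0)


def net_radiation(
    weather: DailyWeather,
    site: SiteGeometry,
    day_of_year: int,
    k_rs: float = KRS_INTERIOR,
    ea_pairing: str = "fao",
) -> dict[str, float]:
    """Net radiation at the grass surface from the daily temperature range.

    With no pyranometer, solar radiation is estimated from the diurnal
    temperature range: R_s = k_rs * sqrt(Tmax - Tmin) * R_a. Clear-sky
    radiation R_so = (0.75 + 2e-5 z) * R_a; net shortwave
    R_ns = (1 - albedo) * R_s; net longwave R_nl from the Stefan-Boltzmann
    law with humidity and cloudiness (R_s / R_so, clipped to [0.25, 1])
    corrections; R_n = R_ns - R_nl.

    Returns a dict with keys R_a, R_s, R_so, R_ns, R_nl, R_n.
    """
    if weather.t_max < weather.t_min:
        raise ValueError("t_max < t_min")
    r_a = extraterrestrial_radiation(site.latitude, day_of_year)
    r_s = k_rs * math.sqrt(weather.t_max - weather.t_min) * r_a
    r_so = (0.75 + 2e-5 * site.elevation_z) * r_a
    r_s = min(r_s, r_so)
    r_ns = (1.0 - GRASS_ALBEDO) * r_s
    e_a = actual_vapor_pressure(
        weather.t_max, weather.t_min, weather.rh_max, weather.rh_min, pairing=ea_pairing
    )
    # cloudiness ratio clipped so R_nl stays finite when R_a (hence R_so) is 0
    ratio = r_s / r_so if r_so > 0.0 else 0.25
    ratio = min(1.0, max(0.25, ratio))
    tmax_k4 = (weather.t_max + 273.16) ** 4
    tmin_k4 = (weather.t_min + 273.16) ** 4
    r_nl = (
        STEFAN_BOLTZMANN
        * 0.5
        * (tmax_k4 + tmin_k4)
        * (0.34 - 0.14 * math.sqrt(e_a))
        * (1.35 * ratio - 0.35)
    )
    return {
        "R_a": r_a,
        "R_s": r_s,
        "R_so": r_so,
        "R_ns": r_ns,
        "R_nl": r_nl,
        "R_n": r_ns - r_nl,
    }


def reference_et0(
    weather: DailyWeather,
    site: SiteGeometry,
    k_rs: float = KRS_INTERIOR,
    ea_pairing: str = "fao",
) -> AtmosphericTerms:
    """Daily grass reference evapotranspiration ET0 and all sub-terms.

    ET0 = [0.408 Delta (R_n - G) + gamma 900/(T+273) u2 (e_s - e_a)]
          / [Delta + gamma (1 + 0.34 u2)]

    with T the daily mean temperature, G = 0 at the daily step, u2 the wind
    speed adjusted to 2 m, and R_n from the temperature-range radiation
    estimate. A (rare) negative numerator is floored at 0 mm/day.
    """
    doy = weather.date.timetuple().tm_yday
    e0_tmax = saturation_vapor_pressure(weather.t_max)
    e0_tmin = saturation_vapor_pressure(weather.t_min)
    e_s = 0.5 * (e0_tmax + e0_tmin)
    e_a = actual_vapor_pressure(
        weather.t_max, weather.t_min, weather.rh_max, weather.rh_min, pairing=ea_pairing
    )
    t_mean = weather.t_mean
    delta = vapor_pressure_slope(t_mean)
    pressure = atmospheric_pressure(site.elevation_z)
    gamma = psychrometric_constant(pressure)
    u2 = wind_to_2m(weather.wind_speed, site.anemometer_height)
    rad = net_radiation(weather, site, doy, k_rs=k_rs, ea_pairing=ea_pairing)
    g = 0.0
    numerator = 0.408 * delta * (rad["R_n"] - g) + gamma * (
        900.0 / (t_mean + 273.0)
    ) * u2 * (e_s - e_a)
    denominator = delta + gamma * (1.0 + 0.34 * u2)
    et0 = max(numerator / denominator, 0.0)
    return AtmosphericTerms(
        e0_tmax=e0_tmax,
        e0_tmin=e0_tmin,
        e_s=e_s,
        e_a=e_a,
        delta=delta,
        pressure_P=pressure,
        gamma=gamma,
        u2=u2,
        R_a=rad["R_a"],
        R_s=rad["R_s"],
        R_so=rad["R_so"],
        R_ns=rad["R_ns"],
        R_nl=rad["R_nl"],
        R_n=rad["R_n"],
        G=g,
        et0=et0,
    )
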