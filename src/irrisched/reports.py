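"""Trial-comparison arithmetic and the season runner.

Reproduces the published two-area trial bookkeeping: seasonal irrigation
totals, water saved and percent-of-traditional usage, per-tree and per-acre
yield comparison with the truncated percent increase, and the national
extrapolation (per-acre values times the 12,355.27 acres under lemon in
Pakistan, with litres converted to cubic feet at 28.3168 L/ft3).

``run_season`` composes the whole pipeline — synthetic or file weather,
ET0, Kc, the water balance and the Warabandi scheduler — into deterministic
delimited-text logs and a plain-text summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .config import RunConfig
from .scheduler import SeasonResult, simulate_season
from .synth import frame_to_weather, generate_weather_season, weather_to_frame

__all__ = [
    "LITRES_PER_CUBIC_FOOT",
    "NATIONAL_LEMON_AREA_ACRES",
    "TrialComparison",
    "ExtrapolationReport",
    "seasonal_totals",
    "compare_trial",
    "extrapolate_national",
    "run_season",
]

LITRES_PER_CUBIC_FOOT = 28.3168
#: ~5000 ha under lemon cultivation in Pakistan, expressed in acres.
NATIONAL_LEMON_AREA_ACRES = 12_355.27


@dataclass(frozen=True)
class TrialComparison:
    """Side-by-side totals of the traditional (A) and scheduled (B) areas."""

    water_a: float
    water_b: float
    water_saved: float
    percent_of_traditional: int
    yield_per_tree_a: float
    yield_per_tree_b: float
    yield_per_acre_a: float
    yield_per_acre_b: float
    yield_per_acre_diff: float
    yield_increase_pct_truncated: int
    yield_increase_pct: float
    revenue_a: float
    revenue_b: float


@dataclass(frozen=True)
class ExtrapolationReport:
    """Per-acre trial values scaled to a national cultivated area."""

    area_acres: float
    total_yield_kg_a: float
    total_yield_kg_b: float
    total_yield_kg_diff: float
    total_yield_tons_a: float
    total_yield_tons_b: float
    total_water_l_a: float
    total_water_l_b: float
    total_water_l_diff: float
    total_water_ft3_a: float
    total_water_ft3_b: float
    total_water_ft3_diff: float


def seasonal_totals(log: Sequence[float] | pd.Series | pd.DataFrame) -> float:
    """Total irrigation volume (L) of an event log.

    Accepts a sequence of event volumes, a Series, or a DataFrame with a
    volume column (``volume_l``, ``area_a_l`` ... — any single column whose
    name contains 'l').
    """
    if isinstance(log, pd.DataFrame):
        candidates = [c for c in log.columns if c == "volume_l" or c.endswith("_l")]
        if len(candidates) != 1:
            raise ValueError(
                f"ambiguous volume column in {list(log.columns)}; pass a Series"
            )
        log = log[candidates[0]]
    values = [float(v) for v in log]
    if any(v < 0 for v in values):
        raise ValueError("irrigation volumes must be >= 0")
    return float(sum(values))


def compare_trial(
    water_a: float,
    water_b: float,
    yield_per_tree: tuple[float, float] = (0.0, 0.0),
    yield_per_acre: tuple[float, float] = (0.0, 0.0),
    revenue: tuple[float, float] = (0.0, 0.0),
) -> TrialComparison:
    """Water-savings and yield comparison between the two trial areas.

    water_saved = A - B; percent_of_traditional = round(100 B / A). The
    yield increase from A to B is reported both truncated to an integer
    percent and to full precision.
    """
    if water_a <= 0.0:
        raise ValueError(f"water_a must be > 0, got {water_a}")
    tree_a, tree_b = yield_per_tree
    acre_a, acre_b = yield_per_acre
    rev_a, rev_b = revenue
    if tree_a > 0:
        pct = 100.0 * (tree_b - tree_a) / tree_a
    elif acre_a > 0:
        pct = 100.0 * (acre_b - acre_a) / acre_a
    else:
        pct = 0.0
    return TrialComparison(
        water_a=water_a,
        water_b=water_b,
        water_saved=water_a - water_b,
        percent_of_traditional=round(100.0 * water_b / water_a),
        yield_per_tree_a=tree_a,
        yield_per_tree_b=tree_b,
        yield_per_acre_a=acre_a,
        yield_per_acre_b=acre_b,
        yield_per_acre_diff=acre_b - acre_a,
        yield_increase_pct_truncated=math.trunc(pct),
        yield_increase_pct=pct,
        revenue_a=rev_a,
        revenue_b=rev_b,
    )


def extrapolate_national(
    yield_per_acre: tuple[float, float],
    water_per_acre: tuple[float, float],
    area_acres: float = NATIONAL_LEMON_AREA_ACRES,
) -> ExtrapolationReport:
    """Scale per-acre trial values to a national area — exact products.

    Totals are per-acre value times area with no intermediate rounding;
    tons are kg / 1000 and cubic feet are litres / 28.3168.
    """
    if area_acres <= 0.0:
        raise ValueError(f"area_acres must be > 0, got {area_acres}")
    ya, yb = yield_per_acre
    wa, wb = water_per_acre
    if min(ya, yb, wa, wb) <= 0.0:
        raise ValueError("per-acre values must be > 0")
    tya, tyb = ya * area_acres, yb * area_acres
    twa, twb = wa * area_acres, wb * area_acres
    return ExtrapolationReport(
        area_acres=area_acres,
        total_yield_kg_a=tya,
        total_yield_kg_b=tyb,
        total_yield_kg_diff=tyb - tya,
        total_yield_tons_a=tya / 1000.0,
        total_yield_tons_b=tyb / 1000.0,
        total_water_l_a=twa,
        total_water_l_b=twb,
        total_water_l_diff=twa - twb,
        total_water_ft3_a=twa / LITRES_PER_CUBIC_FOOT,
        total_water_ft3_b=twb / LITRES_PER_CUBIC_FOOT,
        total_water_ft3_diff=(twa - twb) / LITRES_PER_CUBIC_FOOT,
    )


# ---------------------------------------------------------------------------
# Season runner

_FLOAT_FMT = "%.6f"


def run_season(
    config: RunConfig,
    weather_csv: str | Path | None = None,
    out_dir: str | Path | None = None,
    policy: str = "dss",
) -> dict:
    """Run one season end to end and (optionally) write its logs.

    Weather comes from ``weather_csv`` (delimited text with columns date,
    t_max, t_min, rh_max, rh_min, wind_speed) or, when absent, from the
    seeded synthetic generator in the config. Writes ``daily_log.csv``,
    ``events.csv``, ``weather.csv`` and ``summary.txt`` under ``out_dir``
    with fixed float formatting, so reruns with the same seed are
    byte-identical. Returns {"result": SeasonResult, "summary": str}.
    """
    if weather_csv is not None:
        weather = frame_to_weather(pd.read_csv(weather_csv))
    else:
        weather = generate_weather_season(config.season_spec())

    result = simulate_season(
        weather=weather,
        site=config.site_geometry(),
        crop=config.crop_profile(),
        soil=config.soil_profile(),
        calendar=config.warabandi_calendar(),
        flow=config.flow_spec(),
        policy=policy,
        initial_depletion=config.options.initial_depletion_mm,
        forecast=config.options.forecast,
        forecast_window_k=config.options.forecast_window_k,
    )

    daily = result.daily
    n_events = len(result.events)
    summary_lines = [
        f"season: {daily['date'].iloc[0]} .. {daily['date'].iloc[-1]} ({len(daily)} days)",
        f"policy: {policy}",
        f"total ET0: {daily['et0_mm'].sum():.1f} mm",
        f"total ETc: {daily['etc_mm'].sum():.1f} mm",
        f"irrigation events: {n_events}",
        f"total irrigation: {result.total_irrigation_mm:.1f} mm "
        f"({result.total_irrigation_l:.0f} L)",
        f"max end-of-day depletion: {daily['dr_end_mm'].max():.1f} mm "
        f"(RAW {daily['raw_mm'].iloc[0]:.1f} mm, TAW {daily['taw_mm'].iloc[0]:.1f} mm)",
    ]
    summary = "\n".join(summary_lines) + "\n"

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        daily.to_csv(out / "daily_log.csv", index=False, float_format=_FLOAT_FMT)
        result.events.to_csv(out / "events.csv", index=False, float_format=_FLOAT_FMT)
        weather_to_frame(weather).to_csv(
            out / "weather.csv", index=False, float_format=_FLOAT_FMT
        )
        (out / "summary.txt").write_text(summary)

    return {"result": result, "summary": summary}
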