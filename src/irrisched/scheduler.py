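"""Warabandi-constrained irrigation scheduling.

Under rotational water allocation (Warabandi) a farmer receives canal water
only on fixed turn days (weekly in the study region). The scheduler
projects root-zone depletion forward with a persistence forecast of ETc,
finds the date the D_r >= RAW trigger will fire, and aligns irrigation to
the latest turn on or before that date — water on Monday is delivered the
previous Friday rather than the following one, since depletion past RAW
stresses the crop. Recommendations are expressed interchangeably as depth
(mm), volume (L), run time at the channel flow rate (min) or acre-inches.

``simulate_season`` runs whole seasons under either the demand-driven
policy ("dss") or the traditional every-turn refill policy, and is the
engine behind the comparison reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date as Date, timedelta
from typing import Sequence

import pandas as pd

from .crop import CropProfile, crop_evapotranspiration, kc_on_day
from .met import DailyWeather, SiteGeometry, reference_et0
from .soil import (
    SoilProfile,
    WaterBalanceState,
    advance_day,
    readily_available_water,
    total_available_water,
)

__all__ = [
    "ACRE_INCH_LITRES",
    "WarabandiCalendar",
    "FlowSpec",
    "IrrigationRecommendation",
    "forecast_need_date",
    "align_to_turn",
    "recommend",
    "convert_output",
    "SeasonResult",
    "simulate_season",
]

#: Litres in one acre-inch (one acre flooded one inch deep).
ACRE_INCH_LITRES = 102_790.15
#: Square metres per acre.
ACRE_M2 = 4046.8564224


class NoFeasibleTurnError(ValueError):
    """No water turn exists on or before the projected need date."""


@dataclass(frozen=True)
class WarabandiCalendar:
    """Turn days: periodic from an anchor date, or an explicit date list.

    ``turn_anchor`` is any known turn day; turns repeat every
    ``period_days`` both before and after it. An ``explicit_turns`` list
    (strictly increasing) overrides the periodic rule.
    """

    turn_anchor: Date
    period_days: int = 7
    explicit_turns: tuple[Date, ...] | None = None

    def __post_init__(self) -> None:
        if self.period_days < 1:
            raise ValueError(f"period_days must be >= 1, got {self.period_days}")
        if self.explicit_turns is not None:
            turns = tuple(self.explicit_turns)
            if any(b <= a for a, b in zip(turns, turns[1:])):
                raise ValueError("explicit_turns must be strictly increasing")
            object.__setattr__(self, "explicit_turns", turns)

    def is_turn(self, date: Date) -> bool:
        if self.explicit_turns is not None:
            return date in self.explicit_turns
        return (date - self.turn_anchor).days % self.period_days == 0

    def previous_turn(self, date: Date) -> Date | None:
        """Latest turn on or before `date`, or None."""
        if self.explicit_turns is not None:
            before = [d for d in self.explicit_turns if d <= date]
            return before[-1] if before else None
        offset = (date - self.turn_anchor).days % self.period_days
        return date - timedelta(days=offset)

    def next_turn(self, date: Date) -> Date | None:
        """Earliest turn strictly after `date`, or None."""
        if self.explicit_turns is not None:
            after = [d for d in self.explicit_turns if d > date]
            return after[0] if after else None
        prev = self.previous_turn(date)
        return prev + timedelta(days=self.period_days)


@dataclass(frozen=True)
class FlowSpec:
    """Channel flow rate (L/min) and irrigated field area (m2)."""

    flow_rate: float
    field_area: float

    def __post_init__(self) -> None:
        if self.flow_rate <= 0.0 or self.field_area <= 0.0:
            raise ValueError("flow_rate and field_area must be > 0")


@dataclass(frozen=True)
class IrrigationRecommendation:
    """A turn-aligned irrigation order in every unit the farmer may use.

    1 mm depth over 1 m2 is 1 L, so volume = depth * area; duration is the
    run time at the channel flow rate; stress_warning flags a need date
    whose aligned turn already passed (water arrives late, on the next turn).
    """

    need_date: Date
    turn_date: Date
    depth: float
    volume: float
    duration: float
    acre_inches: float
    stress_warning: bool = False


def forecast_need_date(
    state: WaterBalanceState,
    recent_etc: Sequence[float],
    horizon_days: int,
    k: int = 3,
) -> Date | None:
    """Earliest date projected depletion reaches RAW, or None within horizon.

    Persistence forecast: future daily ETc is the mean of the last `k`
    observed values. If depletion already sits at RAW the need date is
    today; a zero forecast never triggers.
    """
    if horizon_days < 1:
        raise ValueError(f"horizon_days must be >= 1, got {horizon_days}")
    if len(recent_etc) == 0:
        raise ValueError("recent_etc must contain at least one value")
    if state.depletion_dr >= state.raw:
        return state.date
    etc_rate = sum(recent_etc[-k:]) / len(recent_etc[-k:])
    if etc_rate <= 0.0:
        return None
    days = math.ceil((state.raw - state.depletion_dr) / etc_rate)
    if days > horizon_days:
        return None
    return state.date + timedelta(days=days)


def align_to_turn(need_date: Date, calendar: WarabandiCalendar) -> Date:
    """Latest turn on or before the need date (irrigate early, never late)."""
    turn = calendar.previous_turn(need_date)
    if turn is None:
        raise NoFeasibleTurnError(f"no water turn on or before {need_date}")
    return turn


def convert_output(volume_l: float, flow: FlowSpec, unit: str) -> float:
    """Express an irrigation volume as litres, run-time minutes, or acre-inches.

    The water delivered is identical in every unit; conversions are exact
    round trips (volume = duration * flow_rate = acre_inches * 102,790.15).
    """
    if volume_l < 0.0:
        raise ValueError(f"volume_l must be >= 0, got {volume_l}")
    if unit == "volume":
        return volume_l
    if unit == "time":
        return volume_l / flow.flow_rate
    if unit == "acre_inch":
        return volume_l / ACRE_INCH_LITRES
    raise ValueError(f"unknown output unit {unit!r} (expected volume/time/acre_inch)")


def recommend(
    state: WaterBalanceState,
    recent_etc: Sequence[float],
    calendar: WarabandiCalendar,
    flow: FlowSpec,
    horizon_days: int = 30,
    k: int = 3,
) -> IrrigationRecommendation | None:
    """Turn-aligned irrigation recommendation, or None if no projected need.

    The recommended depth is the depletion projected for the turn date
    (refill to field capacity on the day water is actually taken). If the
    aligned turn has already passed relative to the state's date, the next
    turn is recommended instead with a stress warning.
    """
    need = forecast_need_date(state, recent_etc, horizon_days, k=k)
    if need is None:
        return None
    turn = align_to_turn(need, calendar)
    stress = False
    if turn < state.date:
        nxt = calendar.next_turn(state.date - timedelta(days=1))
        if nxt is None:
            raise NoFeasibleTurnError("no upcoming turn in the calendar")
        turn = nxt
        stress = True
    etc_rate = sum(recent_etc[-k:]) / len(recent_etc[-k:])
    depth = min(state.taw, state.depletion_dr + etc_rate * (turn - state.date).days)
    if depth <= 0.0:
        return None
    volume = depth * flow.field_area
    return IrrigationRecommendation(
        need_date=need,
        turn_date=turn,
        depth=depth,
        volume=volume,
        duration=convert_output(volume, flow, "time"),
        acre_inches=convert_output(volume, flow, "acre_inch"),
        stress_warning=stress,
    )


# ---------------------------------------------------------------------------
# Season simulation


@dataclass
class SeasonResult:
    """Daily water-balance log plus the irrigation events of one season run."""

    daily: pd.DataFrame
    events: pd.DataFrame

    @property
    def total_irrigation_l(self) -> float:
        return float(self.events["volume_l"].sum()) if len(self.events) else 0.0

    @property
    def total_irrigation_mm(self) -> float:
        return float(self.events["depth_mm"].sum()) if len(self.events) else 0.0


def _project_need(
    dr: float, raw: float, taw: float, future_etc: Sequence[float]
) -> int | None:
    """Days (0-based offset) until end-of-day depletion first reaches RAW."""
    if dr >= raw:
        return 0
    d = dr
    for i, e in enumerate(future_etc):
        d = min(taw, d + e)
        if d >= raw:
            return i + 1
        if e <= 0 and d < raw and i > 30:
            break
    return None


def simulate_season(
    weather: Sequence[DailyWeather],
    site: SiteGeometry,
    crop: CropProfile,
    soil: SoilProfile,
    calendar: WarabandiCalendar,
    flow: FlowSpec,
    policy: str = "dss",
    initial_depletion: float = 0.0,
    forecast: str = "persistence",
    forecast_window_k: int = 3,
    precipitation: Sequence[float] | None = None,
) -> SeasonResult:
    """Run a whole season of the daily decision loop under one policy.

    Policies
    --------
    ``"dss"``
        Demand-driven: on each turn day, project depletion forward (with
        the persistence forecast, or the realized ETc series when
        ``forecast="perfect"``); irrigate — refilling to field capacity —
        only if the D_r >= RAW trigger would fire before the next turn.
    ``"every-turn"``
        Traditional fixed schedule: refill to field capacity on every turn
        day regardless of need.
    ``"none"``
        No irrigation (bookkeeping only).

    Each day applies ETc first, then any irrigation/precipitation, matching
    the initial/final-depletion convention. Irrigation happens only on turn
    days. Returns the daily state log and the irrigation event log.
    """
    if policy not in ("dss", "every-turn", "none"):
        raise ValueError(f"unknown policy {policy!r}")
    if forecast not in ("persistence", "perfect"):
        raise ValueError(f"unknown forecast mode {forecast!r}")
    if precipitation is None:
        precipitation = [0.0] * len(weather)
    if len(precipitation) != len(weather):
        raise ValueError("precipitation series must match weather length")

    taw = total_available_water(soil, crop.effective_root_depth)
    raw = readily_available_water(taw, crop.depletion_fraction_p)
    state = WaterBalanceState(
        date=weather[0].date, depletion_dr=initial_depletion, taw=taw, raw=raw
    )

    # realized ETc series, filled day by day (perfect foresight precomputes it)
    etc_series: list[float] = []
    if forecast == "perfect":
        for w in weather:
            terms = reference_et0(w, site)
            etc_series.append(
                crop_evapotranspiration(terms.et0, kc_on_day(crop, w.date))
            )

    daily_rows = []
    event_rows = []
    for i, w in enumerate(weather):
        terms = reference_et0(w, site)
        kc = kc_on_day(crop, w.date)
        etc = crop_evapotranspiration(terms.et0, kc)
        if forecast != "perfect":
            etc_series.append(etc)

        dr_start = state.depletion_dr
        final_no_irr = min(taw, dr_start + etc - precipitation[i])
        irrigation = 0.0
        action = ""
        if calendar.is_turn(w.date) and policy != "none":
            if policy == "every-turn":
                irrigation = max(0.0, final_no_irr)
                action = "irrigate (fixed turn)"
            else:
                if forecast == "perfect":
                    future = etc_series[i + 1 :]
                else:
                    rate = sum(etc_series[-forecast_window_k:]) / len(
                        etc_series[-forecast_window_k:]
                    )
                    future = [rate] * 366
                nxt = calendar.next_turn(w.date)
                offset = _project_need(final_no_irr, raw, taw, future)
                if offset is not None and (
                    nxt is None or w.date + timedelta(days=offset) < nxt
                ):
                    irrigation = max(0.0, final_no_irr)
                    action = "irrigate (need before next turn)"
            if irrigation <= 0.0:
                irrigation = 0.0
                action = action or "turn skipped (no need)"

        state = advance_day(state, etc, irrigation, precipitation[i])
        if irrigation > 0.0:
            volume = irrigation * flow.field_area
            event_rows.append(
                {
                    "date": w.date.isoformat(),
                    "depth_mm": irrigation,
                    "volume_l": volume,
                    "duration_min": convert_output(volume, flow, "time"),
                    "acre_inch": convert_output(volume, flow, "acre_inch"),
                }
            )
        daily_rows.append(
            {
                "date": w.date.isoformat(),
                "et0_mm": terms.et0,
                "kc": kc,
                "etc_mm": etc,
                "dr_start_mm": dr_start,
                "dr_end_mm": state.depletion_dr,
                "raw_mm": raw,
                "taw_mm": taw,
                "irrigation_mm": irrigation,
                "precipitation_mm": precipitation[i],
                "percolation_mm": state.percolation,
                "action": action or ("ET only" if not calendar.is_turn(w.date) else "turn skipped (no need)"),
            }
        )

    daily = pd.DataFrame(daily_rows)
    events = pd.DataFrame(
        event_rows,
        columns=["date", "depth_mm", "volume_l", "duration_min", "acre_inch"],
    )
    return SeasonResult(daily=daily, events=events)
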