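"""Root-zone soil-water bookkeeping and the D_r >= RAW irrigation trigger.

The root zone is treated as a single bucket. Total available water
TAW = 1000 (theta_FC - theta_WP) Z_r is the plant-extractable storage (mm);
readily available water RAW = p * TAW is the share the crop can lose before
stress. Depletion D_r (mm below field capacity) grows with crop
evapotranspiration, shrinks with irrigation and rain, and is clipped to
[0, TAW] — water pushed below 0 leaves as deep percolation, recorded so
that the balance closes exactly. Irrigation is flagged the moment the
end-of-day depletion reaches RAW (inclusive).

Within a day ETc is applied first ("final depletion"), then that day's
irrigation and precipitation. When a soil-moisture sensor is present the
day's depletion can instead be anchored from the measured volumetric water
content via ``depletion_from_moisture``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from datetime import date as Date, timedelta

__all__ = [
    "SoilProfile",
    "WaterBalanceState",
    "total_available_water",
    "readily_available_water",
    "depletion_from_moisture",
    "advance_day",
    "irrigation_needed",
    "refill_depth",
]


@dataclass(frozen=True)
class SoilProfile:
    """Volumetric water contents at field capacity and wilting point, m3/m3."""

    theta_fc: float
    theta_wp: float

    def __post_init__(self) -> None:
        if not 0.0 < self.theta_wp < self.theta_fc < 1.0:
            raise ValueError(
                "require 0 < theta_wp < theta_fc < 1, got "
                f"theta_wp={self.theta_wp}, theta_fc={self.theta_fc}"
            )


@dataclass(frozen=True)
class WaterBalanceState:
    """Root-zone depletion on a date, with its TAW/RAW context.

    ``percolation`` records the deep percolation (mm) generated by the
    update that produced this state, so seasonal balances close exactly.
    """

    date: Date
    depletion_dr: float
    taw: float
    raw: float
    percolation: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.raw <= self.taw:
            raise ValueError(f"require 0 < raw <= taw, got raw={self.raw}, taw={self.taw}")
        if not -1e-9 <= self.depletion_dr <= self.taw + 1e-9:
            raise ValueError(
                f"depletion_dr must be in [0, taw], got {self.depletion_dr} (taw={self.taw})"
            )
        if self.percolation < 0.0:
            raise ValueError("percolation must be >= 0")


def total_available_water(soil: SoilProfile, root_depth: float) -> float:
    """TAW = 1000 (theta_FC - theta_WP) Z_r, mm; linear in root depth."""
    if root_depth <= 0.0:
        raise ValueError(f"root_depth must be > 0 m, got {root_depth}")
    span = soil.theta_fc - soil.theta_wp
    if span <= 0.0 or math.isclose(span, 0.0, abs_tol=1e-12):
        raise ValueError("soil has zero water-holding capacity (theta_fc == theta_wp)")
    return 1000.0 * span * root_depth


def readily_available_water(
    taw: float,
    p: float,
    etc_today: float | None = None,
    adjust: bool = False,
) -> float:
    """RAW = p_eff * TAW, mm.

    With ``adjust`` on, the depletion fraction is corrected for evaporative
    demand: p_eff = p + 0.04 (5 - ETc), clamped to [0.1, 0.8] — hot
    high-demand days stress the crop at shallower depletion.
    """
    if taw <= 0.0:
        raise ValueError(f"taw must be > 0, got {taw}")
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    p_eff = p
    if adjust:
        if etc_today is None:
            raise ValueError("etc_today is required when adjust=True")
        p_eff = min(0.8, max(0.1, p + 0.04 * (5.0 - etc_today)))
    return p_eff * taw


def depletion_from_moisture(soil: SoilProfile, theta_mean: float, root_depth: float) -> float:
    """Depletion implied by a measured water content: 1000 (theta_FC - theta) Z_r.

    Clipped to [0, TAW]; readings above field capacity (just after an
    irrigation) read as zero depletion, readings below wilting point as TAW.
    """
    if not 0.0 <= theta_mean <= 1.0:
        raise ValueError(f"theta_mean must be in [0, 1], got {theta_mean}")
    taw = total_available_water(soil, root_depth)
    dr = 1000.0 * (soil.theta_fc - theta_mean) * root_depth
    return min(taw, max(0.0, dr))


def advance_day(
    state: WaterBalanceState,
    etc: float,
    irrigation_depth: float = 0.0,
    precipitation: float = 0.0,
) -> WaterBalanceState:
    """One day of bookkeeping: add ETc, subtract water applied, clip to [0, TAW].

    Water that would drive depletion below zero drains past the root zone
    and is recorded as that day's deep percolation; depletion cannot exceed
    TAW (the bucket is empty). The returned state is dated one day later.
    """
    for v, name in ((etc, "etc"), (irrigation_depth, "irrigation_depth"), (precipitation, "precipitation")):
        if v < 0.0 or not math.isfinite(v):
            raise ValueError(f"{name} must be finite and >= 0, got {v}")
    raw_dr = state.depletion_dr + etc - irrigation_depth - precipitation
    percolation = max(0.0, -raw_dr)
    new_dr = min(state.taw, max(0.0, raw_dr))
    return replace(
        state,
        date=state.date + timedelta(days=1),
        depletion_dr=new_dr,
        percolation=percolation,
    )


def irrigation_needed(state: WaterBalanceState) -> bool:
    """True iff the root-zone depletion has reached RAW (D_r >= RAW, inclusive)."""
    return state.depletion_dr >= state.raw


def refill_depth(state: WaterBalanceState) -> float:
    """Net irrigation depth (mm) that refills the root zone to field capacity."""
    return state.depletion_dr
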