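"""Crop coefficient (Kc) curves and crop evapotranspiration ETc = Kc * ET0.

A crop's water use relative to the grass reference is described by a staged
Kc curve: constant through the initial and mid-season stages, ramping
linearly through development and late-season. Stages are given as
(name, length_days, kc) triples where ``kc`` is the value reached at the
*end* of the stage; the curve holds the first stage's Kc from planting and
interpolates linearly between stage end-points thereafter. Dates beyond the
last stage hold the final Kc — evergreen orchard crops (citrus) carry a
year-round canopy, so the curve never drops to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date
from typing import NamedTuple

__all__ = ["CropStage", "CropProfile", "lemon_profile", "kc_on_day", "crop_evapotranspiration"]


class CropStage(NamedTuple):
    name: str
    length_days: int
    kc: float


@dataclass(frozen=True)
class CropProfile:
    """Stage-wise Kc curve plus the rooting/stress parameters of one crop.

    ``depletion_fraction_p`` is the fraction of total available water the
    crop can extract before stress (FAO convention; 0.5 for citrus).
    """

    crop_name: str
    planting_date: Date
    stages: tuple[CropStage, ...]
    effective_root_depth: float
    depletion_fraction_p: float = 0.5

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("at least one crop stage is required")
        stages = tuple(CropStage(*s) for s in self.stages)
        object.__setattr__(self, "stages", stages)
        for s in stages:
            if s.length_days <= 0:
                raise ValueError(f"stage {s.name!r} length must be > 0 days")
            if s.kc <= 0.0:
                raise ValueError(f"stage {s.name!r} Kc must be > 0")
        if self.effective_root_depth <= 0.0:
            raise ValueError("effective_root_depth must be > 0 m")
        if not 0.0 < self.depletion_fraction_p < 1.0:
            raise ValueError("depletion_fraction_p must be in (0, 1)")

    @property
    def season_length_days(self) -> int:
        return sum(s.length_days for s in self.stages)


def lemon_profile(planting_date: Date) -> CropProfile:
    """Bundled lemon (citrus) profile: Kc within [0.6, 0.8] across stages.

    Four FAO-style stages sized for a ~9-month monitored season; effective
    root depth 1.1 m and p = 0.5, the citrus conventions.
    """
    return CropProfile(
        crop_name="lemon",
        planting_date=planting_date,
        stages=(
            CropStage("initial", 60, 0.65),
            CropStage("development", 60, 0.75),
            CropStage("mid", 90, 0.75),
            CropStage("late", 60, 0.70),
        ),
        effective_root_depth=1.1,
        depletion_fraction_p=0.5,
    )


def kc_on_day(crop: CropProfile, date: Date) -> float:
    """Crop coefficient on a calendar date.

    Piecewise linear between stage end-points: the first stage's Kc holds
    from planting to its end, each later stage ramps linearly from the
    previous stage's Kc to its own, and dates past the last stage hold the
    final Kc.
    """
    if date < crop.planting_date:
        raise ValueError(
            f"date {date} precedes planting date {crop.planting_date}"
        )
    day = (date - crop.planting_date).days
    # breakpoints: (0, kc1), (L1, kc1), (L1+L2, kc2), ...
    xs = [0, crop.stages[0].length_days]
    ys = [crop.stages[0].kc, crop.stages[0].kc]
    for s in crop.stages[1:]:
        xs.append(xs[-1] + s.length_days)
        ys.append(s.kc)
    if day >= xs[-1]:
        return ys[-1]
    for i in range(1, len(xs)):
        if day <= xs[i]:
            frac = (day - xs[i - 1]) / (xs[i] - xs[i - 1])
            return ys[i - 1] + frac * (ys[i] - ys[i - 1])
    return ys[-1]  # unreachable


def crop_evapotranspiration(et0: float, kc: float) -> float:
    """Crop evapotranspiration ETc = Kc * ET0, mm/day."""
    if et0 < 0.0:
        raise ValueError(f"et0 must be >= 0, got {et0}")
    if kc <= 0.0:
        raise ValueError(f"kc must be > 0, got {kc}")
    return kc * et0
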