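# Methods

## Reference evapotranspiration

Daily grass reference evapotranspiration ET0 is computed with the FAO-56
Penman–Monteith combination equation from daily extremes of temperature
and relative humidity, wind speed at a stated anemometer height, and site
geometry (latitude, elevation). Conventions:

- **Mean temperature.** T = (Tmax + Tmin)/2; Δ (slope of the saturation
  curve) is evaluated at T with the coefficient 0.6108 kPa, the same
  constant used in e°(T). Some printed versions of the slope formula carry
  a typographic 0.618; the two formulas must share one constant or the
  equation set is internally inconsistent.
- **Vapour pressure.** e_s is the mean of e°(Tmax) and e°(Tmin). For e_a
  two pairings of the RH extremes circulate; the default here is the
  FAO-56 pairing e°(Tmin)·RHmax + e°(Tmax)·RHmin (night-time maximum RH
  coincides with the minimum temperature), which guarantees e_a ≤ e_s.
  The alternative like-with-like pairing is available via
  `ea_pairing="literal"`. A mean-RH fallback e_a = RHmean/100 · e_s exists
  for stations without extremes.
- **Pressure and γ.** P = 101.3((293 − 0.0065z)/293)^5.26 in kPa and
  γ = 0.665·10⁻³ P kPa/°C (γ ≈ 0.0674 at sea level). Treating P in
  millibars here would inflate γ tenfold and visibly distort ET0.
- **Wind.** u2 = u_z · 4.87/ln(67.8 z − 5.42) where z is the *measurement
  height above ground* (10 m default for third-party wind products), not
  the site elevation; the formula is the FAO log-profile over clipped
  grass and only that reading makes the factor 1 at z = 2 m. Heights at
  or below (1 + 5.42)/67.8 ≈ 0.095 m are rejected (the log argument must
  exceed 1 for a positive factor).
- **Radiation.** With no pyranometer, solar radiation uses the
  temperature-range estimate R_s = kRs √(Tmax − Tmin) · R_a with
  kRs = 0.16 (interior default; 0.19 coastal, configurable), capped at
  clear-sky R_so = (0.75 + 2·10⁻⁵ z) R_a. Albedo is 0.23 (grass
  reference). Net longwave uses the Stefan–Boltzmann form with the
  humidity term 0.34 − 0.14√e_a and cloudiness term 1.35(R_s/R_so) − 0.35,
  the ratio clipped to [0.25, 1] so the expression stays finite on
  zero-radiation (polar-night) days; the sunset-hour-angle cosine is
  clamped to [−1, 1] so R_a itself degrades to 0 there.
- **G = 0** at the daily time step; a rare negative numerator (saturated,
  radiation-free days) is floored at ET0 = 0.

## Crop coefficient

ETc = Kc·ET0. The Kc curve is staged: (name, length, Kc) triples where Kc
is the value reached at the stage end; the first stage is flat and later
stages ramp linearly, giving the classic flat–ramp–flat–ramp FAO shape
when the development stage bridges initial and mid values. Dates past the
last stage hold the final Kc: citrus is evergreen and a monitored season
can outrun the nominal stage table. The bundled lemon profile uses four
stages (60/60/90/60 days at Kc 0.65/0.75/0.75/0.70), all within the
published 0.6–0.8 range for lemon; stage lengths are configurable since
only the range is published. The dual-coefficient split (Kcb + Ke) is out
of scope.

## Soil-water balance

Single-bucket root zone: TAW = 1000(θFC − θWP)Zr mm,
RAW = p·TAW with p = 0.5 by default (the citrus convention; the published
system does not state its value). An optional demand adjustment
p_eff = p + 0.04(5 − ETc), clamped to [0.1, 0.8], is off by default.

Daily update order is ETc first ("final depletion"), then that day's
irrigation and precipitation; depletion is clipped to [0, TAW]. Water
pushed below zero is recorded as deep percolation on the resulting state,
so the closure ΣETc − Σirrigation − Σprecip = ΔDr − Σpercolation holds to
machine precision whenever the TAW ceiling does not bind (when it does —
a crop left to dry past total available water — the unmet ET demand is
deliberately not tracked). Precipitation defaults to zero: the target
regime is arid (< 240 mm/year) and the trial season recorded none.
Irrigation is flagged when end-of-day Dr ≥ RAW, boundary inclusive.

When hourly soil-moisture telemetry is available, depletion can be
re-anchored from the sensed water content via
Dr = 1000(θFC − θ)Zr clipped to [0, TAW]; a noise-free simulated sensor
round-trips to the bookkeeping depletion exactly (this equivalence is a
test invariant).

## Warabandi scheduling

The need date is forecast by persistence: future ETc is the mean of the
last k = 3 observed values (the deployed system's projection method is
not published; persistence is simple and auditable, and a perfect-
foresight mode using the realized series exists for analysis). The need
date is aligned to the **latest turn on or before it** — late water means
stress, early water only means slightly more volume. If that turn has
already passed, the next turn is recommended with a stress warning. The
recommended depth is the depletion projected at the turn date (refill to
field capacity on the day water is taken), capped at TAW.

Output units are exact identities: 1 mm over 1 m² = 1 L;
duration = volume / flow rate; acre-inch = volume / 102,790.15 L (constant
fixed to two decimals so conversions are bit-exact round trips).

Season policies: `dss` irrigates on a turn only when the trigger is
projected to fire before the next turn; `every-turn` refills on every turn
(the traditional baseline); `none` is bookkeeping only. Under weekly turns
whose weekly ΣETc stays below RAW, the perfect-foresight demand policy
provably never ends a day above RAW, and it always uses no more water than
the every-turn baseline.

## Synthetic seasons

The generator emulates a hot semi-arid season: daily mean temperature
follows T̄ + A·cos(2π(doy − 166)/365.25) with a fixed diurnal range split
symmetrically and independent Gaussian noise per channel; RH extremes and
wind are similarly noised and clipped to physical ranges; one seed drives
all channels. The bundled preset (T̄ = 31 °C, A = 12.5 °C, range 14 °C,
noise σ_T = 1 °C, 270 days from 1 February) was calibrated so seasonal
maxima land near 52 °C, the peak reported for the emulated region. The
generator makes no attempt at spell-length statistics, monsoon humidity
structure, or rainfall — passing tests demonstrate the pipeline's
arithmetic and guarantees, not skill against real weather.

The hourly sensor simulator spreads the day's ETc evenly over 24 readings
and applies irrigation after the last reading of its day, so each day's
final reading is the end-of-day state; air channels interpolate the daily
extremes with a diurnal sinusoid (coolest 05:00, warmest 17:00).
Aggregation back to daily uses extrema for temperature and RH and the
arithmetic mean for θ; partial days are skipped with a warning.

## Reporting

The comparison report takes recorded seasonal totals as inputs:
water saved = A − B, percent-of-traditional = round(100·B/A), yield
increase reported both truncated to integer percent and at full precision.
The national extrapolation multiplies per-acre values by the cultivated
area (12,355.27 acres default) with no intermediate rounding; cubic feet
use 28.3168 L/ft³. The bundled 17-event irrigation log's column sums
(96,869 and 45,218 L) differ from the recorded seasonal totals (96,569 and
44,290 L); both are surfaced, neither is silently reconciled, and the
seasonal totals are treated as canonical. The recorded per-area
cubic-foot figures (3410 / 1705 ft³) are not consistent with any single
litre→ft³ factor and are not reproduced.

## Problem sizes and determinism

The test suite and acceptance script run 270-day seasons (the trial
duration), 200-day random sweeps for the ET0 oracle comparison, and
30-day traces for sensor round-trips. All randomness flows through
numpy's `default_rng` seeded from a single integer; season logs are
written with fixed float formatting so identical seeds give byte-identical
files.

## Known limitations

- Single-layer bucket: no capillary rise, runoff, multi-layer soil or
  salinity dynamics.
- Single (not dual) crop coefficient; no climate correction of mid-season
  Kc.
- Daily ET0 only; no measured-solar-radiation input path.
- Persistence forecasting ignores weather trends; a cold front after a
  hot spell over-irrigates by the forecast error.
- The synthetic preset is a stand-in regime, not a reconstruction of any
  particular year's weather.
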