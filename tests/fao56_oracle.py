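"""Independent straight-line FAO-56 daily ET0 reference for oracle tests.

Written directly from the published FAO-56 equation set as one monolithic
function, deliberately sharing no code with the package. Same physical
conventions (Tmin/RHmax-Tmax/RHmin vapour-pressure pairing, temperature-
range solar radiation with k_Rs, albedo 0.23, G = 0) so that any
disagreement with the package flags an implementation defect, not a
convention choice.
"""

from math import acos, cos, exp, log, pi, sin, sqrt, tan


def fao56_daily_et0(
    tmax, tmin, rhmax, rhmin, wind, wind_height, latitude_deg, elevation_m, day_of_year,
    k_rs=0.16,
):
    """Daily grass reference ET0 (mm/day) by the FAO-56 Penman-Monteith chain."""
    tmean = (tmax + tmin) / 2.0

    es_tmax = 0.6108 * exp(17.27 * tmax / (tmax + 237.3))
    es_tmin = 0.6108 * exp(17.27 * tmin / (tmin + 237.3))
    es = (es_tmax + es_tmin) / 2.0
    ea = (es_tmin * rhmax / 100.0 + es_tmax * rhmin / 100.0) / 2.0

    slope = 4098.0 * (0.6108 * exp(17.27 * tmean / (tmean + 237.3))) / (tmean + 237.3) ** 2
    pressure = 101.3 * ((293.0 - 0.0065 * elevation_m) / 293.0) ** 5.26
    gamma = 0.665e-3 * pressure

    u2 = wind * 4.87 / log(67.8 * wind_height - 5.42)

    lat = latitude_deg * pi / 180.0
    dr = 1.0 + 0.033 * cos(2.0 * pi / 365.0 * day_of_year)
    decl = 0.409 * sin(2.0 * pi / 365.0 * day_of_year - 1.39)
    x = -tan(lat) * tan(decl)
    x = max(-1.0, min(1.0, x))
    omega = acos(x)
    ra = (24.0 * 60.0 / pi) * 0.0820 * dr * (
        omega * sin(lat) * sin(decl) + cos(lat) * cos(decl) * sin(omega)
    )
    ra = max(0.0, ra)
    rs = k_rs * sqrt(tmax - tmin) * ra
    rso = (0.75 + 2e-5 * elevation_m) * ra
    rs = min(rs, rso)
    rns = (1.0 - 0.23) * rs
    ratio = rs / rso if rso > 0.0 else 0.25
    ratio = max(0.25, min(1.0, ratio))
    rnl = (
        4.903e-9
        * (((tmax + 273.16) ** 4 + (tmin + 273.16) ** 4) / 2.0)
        * (0.34 - 0.14 * sqrt(ea))
        * (1.35 * ratio - 0.35)
    )
    rn = rns - rnl

    num = 0.408 * slope * rn + gamma * 900.0 / (tmean + 273.0) * u2 * (es - ea)
    den = slope + gamma * (1.0 + 0.34 * u2)
    return max(0.0, num / den)


def fao56_extraterrestrial(latitude_deg, day_of_year):
    """Daily extraterrestrial radiation R_a (MJ m-2 day-1)."""
    lat = latitude_deg * pi / 180.0
    dr = 1.0 + 0.033 * cos(2.0 * pi / 365.0 * day_of_year)
    decl = 0.409 * sin(2.0 * pi / 365.0 * day_of_year - 1.39)
    x = max(-1.0, min(1.0, -tan(lat) * tan(decl)))
    omega = acos(x)
    ra = (24.0 * 60.0 / pi) * 0.0820 * dr * (
        omega * sin(lat) * sin(decl) + cos(lat) * cos(decl) * sin(omega)
    )
    return max(0.0, ra)


def fao56_net_radiation(tmax, tmin, rhmax, rhmin, latitude_deg, elevation_m, day_of_year, k_rs=0.16):
    """Net radiation R_n (MJ m-2 day-1) by the temperature-range chain."""
    es_tmax = 0.6108 * exp(17.27 * tmax / (tmax + 237.3))
    es_tmin = 0.6108 * exp(17.27 * tmin / (tmin + 237.3))
    ea = (es_tmin * rhmax / 100.0 + es_tmax * rhmin / 100.0) / 2.0
    ra = fao56_extraterrestrial(latitude_deg, day_of_year)
    rs = min(k_rs * sqrt(tmax - tmin) * ra, (0.75 + 2e-5 * elevation_m) * ra)
    rso = (0.75 + 2e-5 * elevation_m) * ra
    rns = 0.77 * rs
    ratio = rs / rso if rso > 0.0 else 0.25
    ratio = max(0.25, min(1.0, ratio))
    rnl = (
        4.903e-9
        * (((tmax + 273.16) ** 4 + (tmin + 273.16) ** 4) / 2.0)
        * (0.34 - 0.14 * sqrt(ea))
        * (1.35 * ratio - 0.35)
    )
    return rns - rnl
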