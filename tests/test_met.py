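"""Meteorological core: vapour-pressure terms, wind profile, radiation, ET0."""

import math
from dataclasses import replace
from datetime import date

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import irrisched as ir
from fao56_oracle import fao56_daily_et0, fao56_extraterrestrial, fao56_net_radiation


class TestVaporPressureTerms:
    @pytest.mark.parametrize(
        "t, expected, tol",
        [(0.0, 0.6108, 1e-9), (20.0, 2.338, 1e-3), (30.0, 4.243, 1e-3)],
    )
    def test_saturation_vapor_pressure_hand_values(self, t, expected, tol):
        assert ir.saturation_vapor_pressure(t) == pytest.approx(expected, abs=tol)

    def test_saturation_curve_strictly_increasing(self):
        ts = [-10 + i for i in range(70)]
        es = [ir.saturation_vapor_pressure(t) for t in ts]
        assert all(b > a for a, b in zip(es, es[1:]))

    @pytest.mark.parametrize(
        "tmax, tmin, expected, tol",
        [(20, 20, 2.338, 1e-3), (30, 20, 3.290, 2e-3), (0, 0, 0.6108, 1e-9)],
    )
    def test_mean_saturation_vapor_pressure(self, tmax, tmin, expected, tol):
        assert ir.mean_saturation_vapor_pressure(tmax, tmin) == pytest.approx(expected, abs=tol)

    def test_mean_svp_rejects_inverted_extremes(self):
        with pytest.raises(ValueError):
            ir.mean_saturation_vapor_pressure(10, 20)

    def test_actual_vapor_pressure_saturated_air_equals_es(self):
        ea = ir.actual_vapor_pressure(30, 20, 100, 100)
        assert ea == pytest.approx(ir.mean_saturation_vapor_pressure(30, 20), rel=1e-12)

    def test_actual_vapor_pressure_dry_air_is_zero(self):
        assert ir.actual_vapor_pressure(30, 20, 0, 0) == 0.0

    def test_literal_pairing_matches_direct_evaluation(self):
        ea = ir.actual_vapor_pressure(30, 20, 80, 40, pairing="literal")
        assert ea == pytest.approx(2.165, abs=3e-3)

    def test_fao_pairing_bounded_by_es(self):
        # the default pairing can never exceed the mean saturation pressure
        ea = ir.actual_vapor_pressure(30, 20, 80, 40)
        assert 0.0 <= ea <= ir.mean_saturation_vapor_pressure(30, 20) + 1e-9

    def test_rh_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ir.actual_vapor_pressure(30, 20, 120, 40)

    @pytest.mark.parametrize("t, expected", [(25.0, 0.189), (0.0, 0.0445)])
    def test_slope_hand_values(self, t, expected):
        assert ir.vapor_pressure_slope(t) == pytest.approx(expected, abs=1e-3)

    def test_slope_increasing_over_field_range(self):
        assert ir.vapor_pressure_slope(30) > ir.vapor_pressure_slope(20)

    def test_non_finite_temperature_rejected(self):
        with pytest.raises(ValueError):
            ir.saturation_vapor_pressure(float("nan"))


class TestPressureWind:
    @pytest.mark.parametrize(
        "z, expected, tol",
        [(0.0, 101.3, 1e-9), (100.0, 100.1, 0.05), (2000.0, 79.84, 0.1)],
    )
    def test_atmospheric_pressure(self, z, expected, tol):
        assert ir.atmospheric_pressure(z) == pytest.approx(expected, abs=tol)

    def test_pressure_decreasing_in_elevation(self):
        ps = [ir.atmospheric_pressure(z) for z in (0, 500, 1000, 2000, 4000)]
        assert all(b < a for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize(
        "p, expected", [(101.3, 0.0674), (79.84, 0.0531)]
    )
    def test_psychrometric_constant(self, p, expected):
        assert ir.psychrometric_constant(p) == pytest.approx(expected, abs=2e-4)

    def test_gamma_linear_in_pressure(self):
        assert ir.psychrometric_constant(50.0) * 2 == pytest.approx(
            ir.psychrometric_constant(100.0), rel=1e-12
        )

    def test_wind_adjustment_factor_at_10m(self):
        assert ir.wind_to_2m(1.0, 10.0) == pytest.approx(0.748, abs=1e-3)

    def test_wind_near_identity_at_2m(self):
        assert ir.wind_to_2m(3.0, 2.0) == pytest.approx(3.0006, abs=2e-3)

    def test_calm_wind_stays_zero(self):
        assert ir.wind_to_2m(0.0, 10.0) == 0.0

    def test_wind_height_below_profile_root_rejected(self):
        with pytest.raises(ValueError):
            ir.wind_to_2m(1.0, 0.08)


class TestRadiation:
    def test_polar_night_yields_zero(self):
        assert ir.extraterrestrial_radiation(70.0, 355) == 0.0

    @pytest.mark.parametrize("lat, doy", [(0.0, 81), (24.9, 150), (-35.0, 10), (55.0, 200)])
    def test_extraterrestrial_matches_reference(self, lat, doy):
        assert ir.extraterrestrial_radiation(lat, doy) == pytest.approx(
            fao56_extraterrestrial(lat, doy), abs=0.1
        )

    def test_zero_temperature_range_kills_solar(self, gadap_site):
        w = ir.DailyWeather(date(2018, 5, 30), 30, 30, 80, 50, 2.0)
        rad = ir.net_radiation(w, gadap_site, 150)
        assert rad["R_s"] == 0.0
        assert rad["R_ns"] == 0.0

    def test_net_radiation_matches_reference(self, gadap_site, hot_day):
        rad = ir.net_radiation(hot_day, gadap_site, 150)
        expected = fao56_net_radiation(34, 26, 80, 50, 24.9, 20.0, 150)
        assert rad["R_n"] == pytest.approx(expected, abs=0.2)

    def test_polar_night_radiation_chain_is_zero_and_finite(self):
        site = ir.SiteGeometry(latitude=75.0, elevation_z=10.0)
        w = ir.DailyWeather(date(2018, 12, 21), -5.0, -15.0, 90, 60, 3.0)
        rad = ir.net_radiation(w, site, 355)
        assert rad["R_a"] == rad["R_s"] == rad["R_so"] == rad["R_ns"] == 0.0
        assert math.isfinite(rad["R_n"])

    def test_solar_capped_at_clear_sky(self, gadap_site):
        # a huge diurnal range cannot push R_s past R_so
        w = ir.DailyWeather(date(2018, 5, 30), 45.0, 5.0, 60, 10, 2.0)
        rad = ir.net_radiation(w, gadap_site, 150)
        assert rad["R_s"] <= rad["R_so"] + 1e-12


class TestReferenceET0:
    def test_no_demand_no_evaporation(self, gadap_site):
        # saturated air with no radiation: both numerator terms vanish
        w = ir.DailyWeather(date(2018, 1, 15), 20.0, 20.0, 100, 100, 2.0)
        terms = ir.reference_et0(w, gadap_site)
        assert terms.R_ns == 0.0
        assert terms.e_s == pytest.approx(terms.e_a, rel=1e-12)
        # R_n may be slightly negative (longwave loss); ET0 floored at 0
        assert terms.et0 >= 0.0

    def test_et0_matches_reference_on_hot_day(self, gadap_site, hot_day):
        terms = ir.reference_et0(hot_day, gadap_site)
        expected = fao56_daily_et0(34, 26, 80, 50, 4.0, 10.0, 24.9, 20.0, 150)
        assert terms.et0 == pytest.approx(expected, abs=0.05)

    def test_subterms_recompose_to_et0(self, gadap_site, hot_day):
        t = ir.reference_et0(hot_day, gadap_site)
        tm = hot_day.t_mean
        num = 0.408 * t.delta * (t.R_n - t.G) + t.gamma * 900.0 / (tm + 273.0) * t.u2 * (t.e_s - t.e_a)
        den = t.delta + t.gamma * (1.0 + 0.34 * t.u2)
        assert max(num / den, 0.0) == t.et0

    def test_soil_heat_flux_always_zero(self, gadap_site, hot_day):
        assert ir.reference_et0(hot_day, gadap_site).G == 0.0

    def test_et0_increases_with_vapor_deficit(self, gadap_site):
        dry = ir.DailyWeather(date(2018, 5, 30), 34, 26, 50, 20, 4.0)
        humid = ir.DailyWeather(date(2018, 5, 30), 34, 26, 95, 70, 4.0)
        assert (
            ir.reference_et0(dry, gadap_site).et0
            > ir.reference_et0(humid, gadap_site).et0
        )

    def test_oracle_equivalence_200_random_days(self, gadap_site):
        """Seeded sweep over the physical envelope: |ET0 - oracle| < 0.05 mm/day."""
        import numpy as np

        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(200):
            tmin = rng.uniform(5.0, 44.0)
            tmax = tmin + rng.uniform(0.5, 52.0 - tmin if tmin < 44 else 8.0)
            tmax = min(tmax, 52.0)
            rhmin = rng.uniform(10.0, 90.0)
            rhmax = rng.uniform(rhmin, 100.0)
            u = rng.uniform(0.0, 10.0)
            doy = int(rng.integers(1, 366))
            w = ir.DailyWeather(date(2018, 1, 1).fromordinal(
                date(2018, 1, 1).toordinal() + doy - 1),
                t_max=float(tmax), t_min=float(tmin),
                rh_max=float(rhmax), rh_min=float(rhmin), wind_speed=float(u))
            got = ir.reference_et0(w, gadap_site).et0
            want = fao56_daily_et0(tmax, tmin, rhmax, rhmin, u, 10.0, 24.9, 20.0, doy)
            worst = max(worst, abs(got - want))
        assert worst < 0.05

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        tmin=st.floats(5, 40),
        drange=st.floats(0.5, 12),
        rhmin=st.floats(10, 80),
        rhspan=st.floats(0, 20),
        u=st.floats(0, 10),
    )
    def test_et0_nonnegative_over_physical_envelope(self, tmin, drange, rhmin, rhspan, u):
        site = ir.SiteGeometry(latitude=24.9, elevation_z=20.0, anemometer_height=10.0)
        w = ir.DailyWeather(date(2018, 6, 1), tmin + drange, tmin,
                            min(100.0, rhmin + rhspan), rhmin, u)
        terms = ir.reference_et0(w, site)
        assert terms.et0 >= 0.0
        assert terms.e_a <= terms.e_s + 1e-9
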