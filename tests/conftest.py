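import sys
from datetime import date
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # fao56_oracle importable

import irrisched as ir


@pytest.fixture
def gadap_site() -> ir.SiteGeometry:
    """Karachi-like station: 24.9 N, 20 m elevation, 10 m anemometer."""
    return ir.SiteGeometry(latitude=24.9, longitude=67.1, elevation_z=20.0,
                           anemometer_height=10.0)


@pytest.fixture
def hot_day() -> ir.DailyWeather:
    """A hot pre-monsoon day typical of the site."""
    return ir.DailyWeather(date(2018, 5, 30), t_max=34.0, t_min=26.0,
                           rh_max=80.0, rh_min=50.0, wind_speed=4.0)


@pytest.fixture
def loam_soil() -> ir.SoilProfile:
    return ir.SoilProfile(theta_fc=0.32, theta_wp=0.12)


@pytest.fixture
def lemon() -> ir.CropProfile:
    return ir.lemon_profile(planting_date=date(2018, 2, 1))


@pytest.fixture
def friday_turns() -> ir.WarabandiCalendar:
    """Weekly Friday turns; 2018-02-02 was a Friday."""
    return ir.WarabandiCalendar(turn_anchor=date(2018, 2, 2), period_days=7)


@pytest.fixture
def two_acre_flow() -> ir.FlowSpec:
    """2-acre field fed at 400 L/min."""
    return ir.FlowSpec(flow_rate=400.0, field_area=8093.71)
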