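import numpy as np
import pytest

from cropdistill import default_params, default_scenario, synth_weather
from cropdistill.weather import SEASON_DAYS, WeatherSeries


@pytest.fixture(scope="session")
def params():
    return default_params()


def constant_weather(tmean=28.0, tmax=32.0, s_inc=18.0, day_len=13.0,
                     co2=350.0, grid_id="gX", year_index=0, latitude=36.0):
    """Season of constant daily weather, for analytic checks."""
    n = SEASON_DAYS
    return WeatherSeries(
        grid_id=grid_id,
        year_index=year_index,
        latitude=latitude,
        tmean=np.full(n, tmean),
        tmax=np.full(n, tmax),
        s_incident=np.full(n, s_inc),
        day_len=np.full(n, day_len),
        co2=np.full(n, co2),
    )


@pytest.fixture
def favorable_weather():
    return constant_weather()


@pytest.fixture
def cold_weather():
    return constant_weather(tmean=10.0, tmax=14.0)


@pytest.fixture(scope="session")
def mixed_series():
    """Five fixed synthetic grid-years spanning the scenario space."""
    specs = [
        (33.0, "baseline"),
        (37.0, "baseline"),
        (37.0, "cool_summer"),
        (36.0, "heat_anthesis"),
        (41.0, "cold_region"),
    ]
    return [
        synth_weather(lat, i, default_scenario(name), seed=900 + i,
                      grid_id=f"f{i}")
        for i, (lat, name) in enumerate(specs)
    ]
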