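import datetime as dt

import pytest

import swardsim as ss


@pytest.fixture(scope="session")
def canopy_params():
    return ss.CanopyParameters()


@pytest.fixture(scope="session")
def soil_params():
    return ss.SoilWaterParameters()


@pytest.fixture(scope="session")
def nitrogen_params():
    return ss.NitrogenParameters()


@pytest.fixture(scope="session")
def weather_year():
    """One year of synthetic weather, fixed seed, shared across tests."""
    return ss.synthesize_weather(2021, 52.0, seed=7)


@pytest.fixture()
def base_config():
    """Default run configuration (rainfed, 28-day cuts, no fertilizer)."""
    return ss.load_config(None)


@pytest.fixture()
def fed_config():
    """Irrigated, well-fertilized configuration for productive runs."""
    return ss.load_config(
        None,
        [
            "management.irrigated=1",
            "nitrogen.n_min_init=150",
            "nitrogen.max_uptake=15",
            "management.fertilizer="
            "[{date: 2021-03-15, amount: 100}, {date: 2021-05-15, amount: 100},"
            " {date: 2021-07-15, amount: 100}]",
        ],
    )


def make_record(
    date=dt.date(2021, 6, 1),
    tmin=10.0,
    tmax=20.0,
    radiation=18.0,
    rain=0.0,
    vapour_pressure=None,
    wind=None,
):
    return ss.WeatherRecord(
        date=date,
        tmin=tmin,
        tmax=tmax,
        radiation=radiation,
        rain=rain,
        vapour_pressure=vapour_pressure,
        wind=wind,
    )
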