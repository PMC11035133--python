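"""Shared fixtures: cultivar/soil presets, deterministic weather, and the
session-scoped synthetic study ensemble used by the envirotyping and
property tests."""

import numpy as np
import pytest

import malisorghum as ms
from malisorghum.pipeline import PipelineConfig, demo_sites, run_pipeline

ENSEMBLE_SEED = 11
ENSEMBLE_SEASONS = 20


@pytest.fixture(scope="session")
def csm63e() -> ms.CultivarParams:
    return ms.cultivar_preset("CSM63E")


@pytest.fixture(scope="session")
def csm335() -> ms.CultivarParams:
    return ms.cultivar_preset("CSM335")


@pytest.fixture(scope="session")
def low_soil() -> ms.SoilProfile:
    return ms.soil_preset("low_swhc")


@pytest.fixture(scope="session")
def high_soil() -> ms.SoilProfile:
    return ms.soil_preset("high_swhc")


def make_constant_weather(rain: float = 12.0, tmax: float = 32.0,
                          tmin: float = 22.0, radiation: float = 20.0,
                          latitude: float = 12.5) -> ms.DailyWeatherSeries:
    """A uniform 365-day series: constant forcing, ample water by default."""
    n = 365
    return ms.DailyWeatherSeries(
        site="constant", latitude=latitude, year=2000,
        rain=np.full(n, float(rain)), tmax=np.full(n, float(tmax)),
        tmin=np.full(n, float(tmin)), radiation=np.full(n, float(radiation)))


@pytest.fixture(scope="session")
def wet_weather() -> ms.DailyWeatherSeries:
    return make_constant_weather()


@pytest.fixture(scope="session")
def samanko_weather() -> ms.DailyWeatherSeries:
    site = ms.SiteSpec("Samanko", 12.5, "800-1000", 920.0)
    return ms.generate_season(site, seed=1)


@pytest.fixture(scope="session")
def ensemble():
    """The scaled-down study: 8 Table-like sites (2 per isohyet zone),
    20 seasons each, both soils, both cultivars, clustered jointly."""
    config = PipelineConfig(sites=demo_sites(ENSEMBLE_SEASONS),
                            seed=ENSEMBLE_SEED)
    return run_pipeline(config)
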