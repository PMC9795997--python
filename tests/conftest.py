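import numpy as np
import pandas as pd
import pytest

from needleiso.drivers import BorealScenario, generate_isotope_forcings, generate_meteo
from needleiso.gas_exchange import GasExchangeParams, solve_series
from needleiso.simulate import VariantConfig, run_season

SEED = 7  # fixture seed, fixed a priori for all synthetic-season tests


@pytest.fixture(scope="session")
def scenario():
    return BorealScenario()


@pytest.fixture(scope="session")
def meteo30(scenario):
    return generate_meteo(30, SEED, scenario)


@pytest.fixture(scope="session")
def forcings30(meteo30, scenario):
    return generate_isotope_forcings(meteo30, SEED + 100, scenario)


@pytest.fixture(scope="session")
def gas30(meteo30):
    return solve_series(meteo30, GasExchangeParams())


@pytest.fixture(scope="session")
def meteo90(scenario):
    """Season spanning productive mid-summer and the late dry-down."""
    return generate_meteo(90, SEED, scenario)


@pytest.fixture(scope="session")
def forcings90(meteo90, scenario):
    return generate_isotope_forcings(meteo90, SEED + 100, scenario)


@pytest.fixture(scope="session")
def gas90(meteo90):
    return solve_series(meteo90, GasExchangeParams())


@pytest.fixture(scope="session")
def season90(meteo90, forcings90, gas90):
    return run_season(meteo90, forcings90, VariantConfig(), gas=gas90)


@pytest.fixture(scope="session")
def season90_wet():
    """Season with day-to-day weather variability but no dry-down trend:
    isolates the weather-driven signal the pool weighting integrates."""
    from dataclasses import replace

    sc = BorealScenario()
    wet = replace(sc, theta_dry=sc.theta_wet)
    meteo = generate_meteo(90, SEED, wet)
    forcings = generate_isotope_forcings(meteo, SEED + 100, wet)
    return run_season(meteo, forcings, VariantConfig())


def midday_mean(series: pd.Series) -> pd.Series:
    minutes = series.index.hour * 60 + series.index.minute
    sel = series[(minutes >= 720) & (minutes <= 900)].dropna()
    return sel.groupby(sel.index.normalize()).mean()
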