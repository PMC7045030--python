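import numpy as np
import pandas as pd
import pytest

from heatptb.exposure import build_daily_series
from heatptb.synthetic import generate_dataset, scenario_config


def make_analysis(ds):
    """(analysis series, daily counts) aligned on analysis days, using the
    pre-masking pollutant values."""
    series = build_daily_series(ds.weather, ds.pollutants_true)
    daily = ds.daily_counts()
    analysis = series.loc[series.index.intersection(daily.index)]
    counts = daily.reindex(analysis.index).to_numpy(dtype=float)
    return analysis, counts


@pytest.fixture(scope="session")
def no_mediation_ds():
    return generate_dataset(scenario_config("no_mediation", seed=1, n_years=11))


@pytest.fixture(scope="session")
def no_mediation_analysis(no_mediation_ds):
    return make_analysis(no_mediation_ds)


@pytest.fixture(scope="session")
def null_ds():
    return generate_dataset(scenario_config("null", seed=7, n_years=11))


@pytest.fixture(scope="session")
def null_analysis(null_ds):
    return make_analysis(null_ds)


@pytest.fixture()
def simple_weather():
    """Two seasons of deterministic-looking weather for cheap unit tests."""
    cfg = scenario_config("null", seed=5, n_years=2)
    from heatptb.synthetic import generate_weather

    return generate_weather(cfg)


@pytest.fixture()
def daily_index():
    return pd.date_range("1995-01-01", "1995-12-31", freq="D")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
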