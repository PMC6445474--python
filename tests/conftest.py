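"""Shared fixtures: a small seeded synthetic world reused across tests."""

import warnings

import numpy as np
import pandas as pd
import pytest

from stagedist import synthetic as syn


@pytest.fixture(scope="session")
def env():
    return syn.generate_environment(1, (20, 30))


@pytest.fixture(scope="session")
def truth(env):
    return syn.default_truth(1, env)


@pytest.fixture(scope="session")
def null_truth(env):
    return syn.default_truth(1, env, "null")


@pytest.fixture(scope="session")
def autumn_hauls(env):
    return syn.generate_hauls(env, {"SWC_IBTS": 300, "NIGFS": 200},
                              (2011, 2012), "OCT_NOV", 2)


@pytest.fixture(scope="session")
def zap_age0(env, truth, autumn_hauls):
    """Direct per-stage ZAP observations, ~940 modellable hauls."""
    return syn.simulate_zap_dataset(env, autumn_hauls, truth, "AGE0", 3)


@pytest.fixture(autouse=True)
def _quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_casts(lon, lat, values, year=2011, season="FEB_MAR"):
    return pd.DataFrame({
        "station_id": [f"st{i:03d}" for i in range(len(values))],
        "lon": lon, "lat": lat, "year": year, "season": season,
        "pressure": 50.0, "temperature": values, "salinity": 34.5})
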