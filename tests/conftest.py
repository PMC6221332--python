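import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import heatthresh as ht

settings.register_profile("det", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("det")


@pytest.fixture(scope="session")
def additive_model() -> ht.MarsModel:
    """Published all-visitor hinge model (AvgTmaxLag1 / Nindex1 knots)."""
    return ht.load_published_model("additive")


@pytest.fixture(scope="session")
def interaction_model() -> ht.MarsModel:
    """Published second-order interaction model."""
    return ht.load_published_model("interaction")


@pytest.fixture()
def toy_daily() -> pd.DataFrame:
    """Five consecutive days of plausible single-station summer weather."""
    tmax = [30.0, 31.0, 33.0, 35.0, 34.0]
    tavg = [26.0, 27.0, 28.5, 30.0, 29.0]
    return pd.DataFrame(
        {
            "station": "S1",
            "date": pd.date_range("2016-08-01", periods=5, freq="D"),
            "tmin": [23.0, 24.0, 25.0, 26.0, 25.5],
            "tavg": tavg,
            "tmax": tmax,
            "rhum": [70.0, 65.0, 60.0, 55.0, 58.0],
            "precip": [0.0, 2.5, 0.0, 0.0, 1.0],
            "wind": [1.2, 1.5, 1.0, 0.8, 1.1],
            "sol_max": [2.5, 2.0, 3.0, 3.2, 2.8],
            "sol_vol": [15.0, 12.0, 20.0, 22.0, 18.0],
        }
    )


@pytest.fixture()
def hinge_data():
    """n=200 draws from y = 2*max(x-5,0) + small noise, plus a decoy."""
    rng = np.random.default_rng(42)
    x = rng.uniform(0.0, 10.0, 200)
    z = rng.normal(size=200)
    y = 2.0 * np.maximum(x - 5.0, 0.0) + rng.normal(0.0, 0.05, 200)
    return pd.DataFrame({"x": x, "z": z}), y
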