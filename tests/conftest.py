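import numpy as np
import pandas as pd
import pytest

import climpenalty as cp


@pytest.fixture(scope="session")
def flat_truth():
    """Small noise-free flat-beta domain: estimator must recover beta exactly."""
    return cp.make_truth(seed=7, shape=(6, 8), years=(2000, 2008),
                         scenario="flat", noise_seasonal_sd=0.0)


@pytest.fixture(scope="session")
def flat_fields(flat_truth):
    return cp.simulate_fields(flat_truth)


@pytest.fixture(scope="session")
def flat_seasonal(flat_fields):
    tmean = (flat_fields["tmax"] + flat_fields["tmin"]) / 2.0
    return {
        "pm_jja": cp.grid_seasonal_means(flat_fields["pm25"], "JJA"),
        "o3_jja": cp.grid_seasonal_means(flat_fields["o3"], "JJA"),
        "t_jja": cp.grid_seasonal_means(tmean, "JJA"),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20160601)


def daily_series(values, start="2000-01-01"):
    idx = pd.date_range(start, periods=len(values), freq="D")
    return pd.Series(values, index=idx)
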