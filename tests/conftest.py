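import numpy as np
import pandas as pd
import pytest

from patsep.cohort import default_config, simulate_cohort


@pytest.fixture(scope="session")
def cfg():
    """Default generator configuration (moment-matched)."""
    return default_config()


@pytest.fixture(scope="session")
def cohort500(cfg):
    """A mid-sized default cohort shared across read-only tests."""
    return simulate_cohort(cfg, seed=20, n=500)


@pytest.fixture(scope="session")
def cohort53(cfg):
    """A study-scale cohort (three strata, 18/18/17)."""
    return simulate_cohort(cfg, seed=21, n=53)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_linear_data(n=200, slope=2.0, noise=0.0, seed=0):
    r = np.random.default_rng(seed)
    x = r.uniform(0.0, 1.0, n)
    y = 1.0 + slope * x + (r.normal(0.0, noise, n) if noise else 0.0)
    return pd.DataFrame({"x": x, "y": y})
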