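import numpy as np
import pandas as pd
import pytest

from edcast import SyntheticConfig, generate_scenario
from edcast.weekly import WeeklySeries


def make_series(values, name="x", start="2009-07-12"):
    """WeeklySeries on a fresh Sunday grid."""
    values = np.asarray(values, dtype=float)
    grid = pd.date_range(start, periods=len(values), freq="7D")
    return WeeklySeries(pd.DatetimeIndex(grid), values, name)


@pytest.fixture(scope="session")
def default_scenario():
    """One default synthetic scenario shared by read-only tests."""
    return generate_scenario(SyntheticConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
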