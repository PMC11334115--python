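import numpy as np
import pandas as pd
import pytest

from uhimort import SyntheticConfig, build_synthetic
from uhimort.pipeline import analyse


def small_config(**overrides) -> SyntheticConfig:
    """A fast study system: 9x9 grid, 8 days, few stations."""
    kwargs = dict(grid_shape=(9, 9), n_days=8, heatwave_peak_day=4,
                  uhii_length_scale=3.0, population_length_scale=2.0,
                  n_official=4, n_pws=8, seed=7)
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


@pytest.fixture(scope="session")
def bundle():
    return build_synthetic(small_config())


@pytest.fixture(scope="session")
def results(bundle):
    return analyse(bundle.inputs)


@pytest.fixture
def daily_series():
    """A 30-day daily exposure series with variation above/below 18.9."""
    rng = np.random.default_rng(11)
    idx = pd.date_range("2022-07-01", periods=30, freq="D")
    return pd.Series(20.0 + 4.0 * np.sin(np.arange(30) / 4.0)
                     + rng.normal(0, 1.5, 30), index=idx)
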