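import numpy as np
import pandas as pd
import pytest

from edflow.core_data import FEATURE_KEYS, TimeSeriesDataset
from edflow.synthetic import GeneratorConfig, generate_arrivals


def make_frame(y, start="2020-01-01", **feature_overrides) -> pd.DataFrame:
    """Minimal valid daily frame around a given count vector."""
    y = np.asarray(y)
    n = len(y)
    data = {"date": pd.date_range(start, periods=n, freq="D"), "y": y}
    t = np.arange(n)
    defaults = {
        "X1": 1395 + t // 365, "X2": 1, "X3": 1, "X4": (t % 7) + 1,
        "X5": np.isin((t % 7) + 1, (1, 6, 7)).astype(int),
        "X6": 0, "X7": 0, "X8": 0,
        "X9": 20.0, "X10": 10.0, "X11": 15.0, "X12": 10.0,
        "X13": 12.0, "X14": 5.0, "X15": 0.0, "X16": 50.0, "X17": 8.0,
    }
    defaults.update(feature_overrides)
    for k in FEATURE_KEYS:
        v = defaults[k]
        data[k] = np.full(n, v) if np.isscalar(v) else np.asarray(v)
    return pd.DataFrame(data)


def make_dataset(y, **feature_overrides) -> TimeSeriesDataset:
    return TimeSeriesDataset(make_frame(y, **feature_overrides))


@pytest.fixture(scope="session")
def synth_ds() -> TimeSeriesDataset:
    """Default synthetic world at full three-year scale."""
    return generate_arrivals(GeneratorConfig(n_days=1092, seed=0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
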