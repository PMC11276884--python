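import numpy as np
import pandas as pd
import pytest

from envrank.tables import FeatureTable


def make_table(features: dict, targets: dict | None = None, start: str = "2015-01-01") -> FeatureTable:
    """Build a FeatureTable from plain column dicts with a daily calendar."""
    n = len(next(iter(features.values())))
    if targets is None:
        targets = {"y": np.zeros(n, dtype=int) + 1}
    dates = pd.date_range(start, periods=n, freq="D")
    return FeatureTable(dates, pd.DataFrame(features), pd.DataFrame(targets))


class StubModel:
    """Deterministic prediction function with a declared feature layout.

    Stands in for a fitted forest wherever an importance measure only needs
    ``feature_names`` and ``predict``.
    """

    def __init__(self, feature_names, fn, target: str = "y"):
        self.feature_names = list(feature_names)
        self._fn = fn
        self.target = target

    def predict(self, X):
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        return np.asarray(self._fn(X), dtype=float)


@pytest.fixture
def stub_model_factory():
    return StubModel


@pytest.fixture
def make_table_factory():
    return make_table


@pytest.fixture(scope="session")
def trend_sine_series():
    """Line + annual sinusoid + Gaussian noise: the known-components fixture."""
    rng = np.random.default_rng(42)
    n = 1460
    t = np.arange(n, dtype=float)
    trend = 2.0 + 0.01 * t
    seasonal = 5.0 * np.sin(2 * np.pi * t / 365.0)
    noise = rng.normal(0.0, 0.5, n)
    return {
        "series": trend + seasonal + noise,
        "trend": trend,
        "seasonal": seasonal,
        "n": n,
        "period": 365,
    }
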