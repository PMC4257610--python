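import numpy as np
import pandas as pd
import pytest

from mosqspec import TimeSeries, load_species


def make_ts(values, start="2010-01-01", delta_t=1.0, label="x"):
    freq = "D" if delta_t == 1.0 else f"{int(delta_t)}D"
    dates = pd.date_range(start, periods=len(values), freq=freq)
    return TimeSeries(dates, np.asarray(values, dtype=float),
                      delta_t=delta_t, label=label)


@pytest.fixture
def ts_factory():
    return make_ts


@pytest.fixture
def ae_vexans():
    return load_species("ae_vexans")


@pytest.fixture
def cs_melanura():
    return load_species("cs_melanura")


@pytest.fixture
def dft_oracle():
    """Direct O(N^2) projection onto sinusoids: power_i = a_i^2 + b_i^2."""

    def oracle(x):
        x = np.asarray(x, dtype=float)
        n = len(x)
        t = np.arange(n)
        powers = []
        for i in range(1, n // 2 + 1):
            a = 2.0 / n * np.sum(x * np.cos(2 * np.pi * i * t / n))
            b = 2.0 / n * np.sum(x * np.sin(2 * np.pi * i * t / n))
            powers.append(a * a + b * b)
        return np.array(powers)

    return oracle


def ar1_series(phi, n, seed, sd=1.0):
    rng = np.random.default_rng(seed)
    x = np.zeros(n)
    x[0] = rng.normal(0, sd / np.sqrt(1 - phi**2))
    eps = rng.normal(0, sd, size=n)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i]
    return make_ts(x, label=f"ar1({phi})")


@pytest.fixture
def ar1_factory():
    return ar1_series
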