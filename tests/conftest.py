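import numpy as np
import pytest

from synchwave import SpatioTemporalSeries, clean_series, transform_series

SITES = ["AQ", "IV", "EC", "AB", "SC"]


def make_series(values, t0="2009-01"):
    values = np.asarray(values, dtype=float)
    return SpatioTemporalSeries(values, SITES[: values.shape[0]], t0=t0)


def seasonal_noise(rng, n_sites=5, T=132, period=12.0, amp=2.0, noise=1.0,
                   phase=0.0):
    """Shared seasonal cosine plus independent white noise per site."""
    t = np.arange(T)
    return (
        amp * np.cos(2 * np.pi * t / period + phase)[None, :]
        + noise * rng.standard_normal((n_sites, T))
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def seasonal_series(rng):
    return clean_series(make_series(seasonal_noise(rng, noise=0.5)))


@pytest.fixture
def seasonal_fields(seasonal_series):
    return transform_series(seasonal_series)
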