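import numpy as np
import pytest

from physiomot import TimestampedSeries, VisitParams, generate_trivariate_signals


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_series(t, v=None):
    t = np.asarray(t, dtype=float)
    if v is None:
        v = np.zeros_like(t)
    return TimestampedSeries(t, np.asarray(v, dtype=float))


@pytest.fixture
def gappy_ar1():
    """Stationary AR(1) on a 1-s grid with three gaps of different lengths."""
    rng = np.random.default_rng(7)
    n = 4000
    x = np.zeros(n)
    eps = rng.normal(0, 1, n)
    for i in range(1, n):
        x[i] = 0.8 * x[i - 1] + eps[i]
    t = np.arange(n, dtype=float)
    keep = np.ones(n, dtype=bool)
    for lo, hi in [(500, 550), (1500, 1535), (2800, 2880)]:
        keep[lo:hi] = False
    return TimestampedSeries(t[keep], x[keep])


@pytest.fixture(scope="session")
def short_visit():
    """A 48-h gap-free synthetic visit shared across feature tests."""
    p = VisitParams(patient_id="P01", visit_id="P01V1", cgis=3, seed=42)
    return generate_trivariate_signals(p)
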