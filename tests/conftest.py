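import numpy as np
import pytest

from robustfc import TimeSeries, canonical_hrf, hemodynamic_convolve, simulate_neural_pair


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def white_pair(rng):
    a = TimeSeries(rng.standard_normal(3000), 1.0, "A")
    b = TimeSeries(rng.standard_normal(3000), 1.0, "B")
    return a, b


def make_ar_series(coeffs, n, seed, fs=1.0):
    """Forward-simulate an AR process driven by known Gaussian innovations."""
    rng = np.random.default_rng(seed)
    coeffs = np.asarray(coeffs, dtype=float)
    p = coeffs.size
    burn = 10 * max(p, 1)
    e = rng.standard_normal(n + burn)
    y = np.zeros(n + burn)
    for t in range(p, n + burn):
        y[t] = (coeffs @ y[t - p : t][::-1] + e[t]) if p else e[t]
    return TimeSeries(y[burn:], fs), e[burn:]


@pytest.fixture
def hemodynamic_pair_factory():
    """Null (rho=0) HRF-convolved pair at a given rate and seed."""

    def make(fs, seed, n=3000, rho=0.0):
        hrf = canonical_hrf(fs)
        a, b = simulate_neural_pair(n, rho, seed, fs)
        return hemodynamic_convolve(a, hrf), hemodynamic_convolve(b, hrf)

    return make


def child_seed(*key):
    return int(np.random.SeedSequence(list(key)).generate_state(1)[0] % 2**31)
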