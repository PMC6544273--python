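import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ring_mask():
    """3x3 solid block with the center pixel removed (one hole)."""
    m = np.ones((3, 3), dtype=int)
    m[1, 1] = 0
    return m


def random_mask(rng, max_side=12):
    h = int(rng.integers(1, max_side + 1))
    w = int(rng.integers(1, max_side + 1))
    density = rng.uniform(0.1, 0.9)
    return (rng.random((h, w)) < density).astype(int)


@pytest.fixture
def ph_simulator():
    """Factory for proportional-hazards data with exponential baseline.

    Returns (X DataFrame, time, event) with a single covariate of known
    log-hazard ``beta`` and roughly the requested censoring fraction.
    """

    def make(n, beta, censoring=0.2, seed=0, binary=True, baseline_rate=0.01):
        gen = np.random.default_rng(seed)
        x = gen.integers(0, 2, n).astype(float) if binary else gen.standard_normal(n)
        t = gen.exponential(1.0, n) / (baseline_rate * np.exp(beta * x))
        if censoring > 0:
            # Exp censoring: P(C < T) = r / (r + rate) per subject, on average
            rate_mean = baseline_rate * float(np.exp(beta * x).mean())
            r = rate_mean * censoring / (1.0 - censoring)
            c = gen.exponential(1.0 / r, n)
        else:
            c = np.full(n, np.inf)
        time = np.minimum(t, c)
        event = (t <= c).astype(int)
        return pd.DataFrame({"x": x}), time, event

    return make
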