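import numpy as np
import pytest

from cpgc.signal_prep import standardize_array


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def white_series(rng):
    """Standardized independent white series, T x k."""
    return standardize_array(rng.normal(size=(229, 4)))


def simulate_var(coefs, T, rng, mixing=None, burn=200, sd=1.0):
    """Reference VAR simulator used by tests (independent of the package's
    generator loop)."""
    coefs = np.asarray(coefs, dtype=float)
    p, k, _ = coefs.shape
    total = T + burn
    e = rng.normal(0.0, sd, size=(total, k))
    if mixing is not None:
        e = e @ np.asarray(mixing).T
    x = np.zeros((total, k))
    x[:p] = e[:p]
    for t in range(p, total):
        acc = e[t].copy()
        for n in range(1, p + 1):
            acc += coefs[n - 1] @ x[t - n]
        x[t] = acc
    return x[burn:]
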