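import numpy as np
import pytest

from pcwa import Trace


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def gaussian_trace(centers, sigma, amp, n_bins, dt, bg=0.0):
    """Deterministic trace of Gaussian peaks (shared test helper)."""
    t = np.arange(n_bins) * dt
    counts = np.full(n_bins, float(bg))
    centers = np.atleast_1d(centers)
    amps = np.broadcast_to(np.atleast_1d(amp), centers.shape)
    sigmas = np.broadcast_to(np.atleast_1d(sigma), centers.shape)
    for c, a, s in zip(centers, amps, sigmas):
        counts += a * np.exp(-((t - c) ** 2) / (2 * s * s))
    return Trace(counts=counts, dt=dt)
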