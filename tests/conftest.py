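import numpy as np
import pytest

from autonom.model import Hyperparams, SegmentParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def hp():
    return Hyperparams()


@pytest.fixture
def hp_notrend():
    return Hyperparams(include_trend=False)


@pytest.fixture
def small_segment(rng):
    """A 60-point single-sinusoid segment with known parameters."""
    times = np.arange(1, 61, dtype=float)
    omega = np.array([0.1])
    beta = np.array([0.5, 0.0, 1.2, -0.7])  # intercept, slope, cos, sin
    sigma2 = 0.25
    y = (
        beta[0]
        + beta[1] * times
        + beta[2] * np.cos(2 * np.pi * omega[0] * times)
        + beta[3] * np.sin(2 * np.pi * omega[0] * times)
        + np.sqrt(sigma2) * rng.standard_normal(times.size)
    )
    return y, times, SegmentParams(omega, beta, sigma2)


@pytest.fixture
def sine_data(rng):
    """A 300-point two-regime sinusoid series with a change-point at 150."""
    from autonom.simulate import SimulationSpec, simulate_piecewise_sinusoid

    spec = SimulationSpec(
        n=300,
        changepoints=[150],
        segments=[
            {"omega": [0.05], "beta": [0.0, 1.0, 1.0], "sigma": 1.0},
            {"omega": [0.12], "beta": [0.0, 1.0, 1.0], "sigma": 1.0},
        ],
    )
    return simulate_piecewise_sinusoid(spec, rng)
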