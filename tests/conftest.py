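import numpy as np
import pytest

from emdcast import synthetic
from emdcast.series import TimeSeries


@pytest.fixture(scope="session")
def default_series() -> TimeSeries:
    """The standard simulated 9-year outpatient series (seed 1)."""
    return synthetic.generate(synthetic.SimConfig(seed=1))


@pytest.fixture(scope="session")
def sine_trend_signal() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """sin(2*pi*t/16) + 0.02 t on t = 0..127, with its two true parts."""
    t = np.arange(128.0)
    sine = np.sin(2 * np.pi * t / 16)
    trend = 0.02 * t
    return sine + trend, sine, trend


@pytest.fixture(scope="session")
def two_sine_signal() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fast + slow sine (period ratio 1:8) plus a constant offset."""
    t = np.arange(128.0)
    fast = np.sin(2 * np.pi * t / 8)
    slow = 0.5 * np.sin(2 * np.pi * t / 64)
    return fast + slow + 5.0, fast, slow
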