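"""Shared fixtures: seeded RNG and the figure-analogue synthetic series that
drive the end-to-end tests (every generator is deterministic under its seed).
"""

import numpy as np
import pytest

from serialrhythm import TimeSeries, synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sinusoid_t12():
    """Sinusoid with period 12 samples and a constant offset (section-length
    artifact demo)."""
    n = 120
    return TimeSeries(5.0 + 2.0 * np.cos(2 * np.pi * np.arange(n) / 12.0), dt=60.0)


@pytest.fixture
def phase_delay_series():
    """Sinusoid with a -6 h phase step in the middle of the series."""
    return synth.phase_program(
        duration=20 * 1440.0,
        dt=15.0,
        period=1440.0,
        schedule=[(10 * 1440.0, -360.0)],
        amplitude=1.0,
        mesor=2.0,
    )


@pytest.fixture
def wrapped_square():
    """Square wave straddling the section boundary (center-of-gravity
    artifact construction): active 20:00-04:00 in a 24-sample cycle."""
    y = np.zeros(24)
    y[19:] = 1.0
    y[:4] = 1.0
    return y


@pytest.fixture
def shape_morph_series():
    """Square-to-sine morph, 40 cycles of 24 hourly samples."""
    return synth.shape_morph(duration=40 * 1440.0, dt=60.0, period=1440.0)


@pytest.fixture
def two_component_series():
    """Equal-amplitude components at 1260 and 1540 min, dt = 15 min."""
    return synth.two_component(
        duration=14400.0, dt=15.0, period1=1260.0, period2=1540.0
    )


@pytest.fixture
def period_step_series():
    """Period protocol stepping from 1440 to 1500 min mid-series."""
    return synth.period_program(
        duration=30 * 1440.0,
        dt=15.0,
        schedule=[(0.0, 1440.0), (15 * 1440.0, 1500.0)],
        mesor=1.0,
    )


@pytest.fixture
def drift_protocol():
    """Factory for free-running series (period 25 h analyzed at 24 h): a
    1 h/day phase drift, one noisy replicate per seed."""

    def make(seed: int, n_days: int = 20, snr: float = 8.0):
        ts = synth.sinusoid(
            duration=n_days * 1440.0, dt=15.0, period=1500.0, amplitude=1.0, mesor=1.0
        )
        return synth.add_noise(ts, snr=snr, amplitude=1.0, seed=seed)

    return make
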