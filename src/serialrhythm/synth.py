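"""Seeded synthetic-rhythm generator.

Every example pattern used in tests and demos is produced here so that the
whole toolkit is testable without external recordings: plain and
phase/period-programmed sinusoids, square activity patterns, square-to-sine
shape morphs, ultradian-to-circadian morphs, two-component series with
close periods, white/pink noise and Poisson count emulation.  A fixed seed
fully determines each output.

SNR is defined as rhythm amplitude divided by the noise standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import TimeSeries, ValidationError

__all__ = [
    "SynthSpec",
    "generate",
    "sinusoid",
    "square_wave",
    "two_component",
    "phase_program",
    "period_program",
    "shape_morph",
    "ultradian_morph",
    "white_noise",
    "pink_noise",
    "poisson_counts",
    "add_noise",
]

_TWO_PI = 2.0 * np.pi

_KINDS = (
    "sinusoid",
    "square",
    "two_component",
    "phase_program",
    "period_program",
    "shape_morph",
    "ultradian_morph",
    "pink_noise",
    "white_noise",
    "poisson_counts",
)


@dataclass
class SynthSpec:
    """Declarative description of a synthetic series."""

    kind: str
    duration: float  # minutes
    dt: float  # minutes
    period: float = 1440.0  # minutes
    amplitude: float = 1.0
    mesor: float = 0.0
    duty: float = 0.5
    period2: float | None = None
    amplitude2: float | None = None
    schedule: Sequence[tuple[float, float]] = field(default_factory=list)
    snr: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValidationError(f"unknown synthetic kind {self.kind!r}")
        if self.duration <= 0 or self.dt <= 0:
            raise ValidationError("duration and dt must be > 0")


def _times(duration: float, dt: float) -> np.ndarray:
    n = int(round(duration / dt))
    if n < 1:
        raise ValidationError("duration shorter than one sample")
    return np.arange(n) * dt


def sinusoid(
    duration: float,
    dt: float,
    period: float,
    amplitude: float = 1.0,
    mesor: float = 0.0,
    peak_time: float = 0.0,
) -> TimeSeries:
    """mesor + amplitude * cos(2*pi*(t - peak_time)/period)."""
    t = _times(duration, dt)
    v = mesor + amplitude * np.cos(_TWO_PI * (t - peak_time) / period)
    return TimeSeries(v, dt, name=f"sinusoid_T{period:g}")


def square_wave(
    duration: float,
    dt: float,
    period: float,
    amplitude: float = 1.0,
    mesor: float = 0.0,
    duty: float = 0.5,
    onset_time: float = 0.0,
) -> TimeSeries:
    """Activity block of width duty*period starting at onset_time each cycle;
    high level mesor + amplitude, low level mesor."""
    if not (0 < duty < 1):
        raise ValidationError("duty must be in (0, 1)")
    t = _times(duration, dt)
    phase = ((t - onset_time) % period) / period
    v = mesor + amplitude * (phase < duty)
    return TimeSeries(v.astype(float), dt, name=f"square_T{period:g}")


def two_component(
    duration: float,
    dt: float,
    period1: float,
    period2: float,
    amplitude1: float = 1.0,
    amplitude2: float = 1.0,
    mesor: float = 0.0,
) -> TimeSeries:
    """Sum of two sinusoids with close periods (e.g. 1260 and 1540 min)."""
    t = _times(duration, dt)
    v = (
        mesor
        + amplitude1 * np.cos(_TWO_PI * t / period1)
        + amplitude2 * np.cos(_TWO_PI * t / period2)
    )
    return TimeSeries(v, dt, name=f"two_component_{period1:g}_{period2:g}")


def phase_program(
    duration: float,
    dt: float,
    period: float,
    schedule: Sequence[tuple[float, float]],
    amplitude: float = 1.0,
    mesor: float = 0.0,
) -> TimeSeries:
    """Sinusoid with programmed step phase shifts.

    ``schedule`` lists (time_minutes, shift_minutes) pairs: from each listed
    time onward the waveform is delayed by the (cumulative) shift.  A shift
    scheduled beyond the series is a validation error.
    """
    t = _times(duration, dt)
    offset = np.zeros_like(t)
    for when, shift in schedule:
        if when < 0 or when > duration:
            raise ValidationError(f"scheduled shift at {when} is outside the series")
        offset[t >= when] += shift
    v = mesor + amplitude * np.cos(_TWO_PI * (t - offset) / period)
    return TimeSeries(v, dt, name="phase_program")


def period_program(
    duration: float,
    dt: float,
    schedule: Sequence[tuple[float, float]],
    amplitude: float = 1.0,
    mesor: float = 0.0,
) -> TimeSeries:
    """Piecewise-constant period protocol (period steps / jet-lag analogues).

    ``schedule`` lists (start_time_minutes, period_minutes) segments; the
    first entry must start at 0.  Phase is integrated so the waveform is
    continuous across period changes.
    """
    if not schedule or schedule[0][0] != 0:
        raise ValidationError("schedule must start at time 0")
    t = _times(duration, dt)
    inst_period = np.empty_like(t)
    for start, period in schedule:
        if period <= 0:
            raise ValidationError("periods must be > 0")
        inst_period[t >= start] = period
    phase = np.cumsum(_TWO_PI * dt / inst_period)
    phase = np.concatenate([[0.0], phase[:-1]])
    v = mesor + amplitude * np.cos(phase)
    return TimeSeries(v, dt, name="period_program")


def shape_morph(
    duration: float,
    dt: float,
    period: float,
    amplitude: float = 1.0,
    mesor: float = 0.0,
) -> TimeSeries:
    """Symmetric square wave morphing linearly into a sinusoid of the same
    period and fundamental amplitude over the series.  The square phase is
    offset by half a sample so no sample falls exactly on a zero crossing
    (keeping the waveform exactly symmetric when period/dt is even)."""
    t = _times(duration, dt)
    frac = t / t[-1] if t.size > 1 else np.zeros_like(t)
    square = amplitude * np.sign(np.cos(_TWO_PI * (t + dt / 2.0) / period))
    sine = amplitude * np.cos(_TWO_PI * t / period)
    v = mesor + (1 - frac) * square + frac * sine
    return TimeSeries(v, dt, name="shape_morph")


def ultradian_morph(
    duration: float,
    dt: float,
    period: float,
    ultradian_divisor: int = 8,
    amplitude: float = 1.0,
    mesor: float = 0.0,
) -> TimeSeries:
    """Power migrating from an ultradian component (period/divisor) to the
    fundamental over the series (immature-to-adult pattern analogue)."""
    t = _times(duration, dt)
    frac = t / t[-1] if t.size > 1 else np.zeros_like(t)
    fast = amplitude * np.cos(_TWO_PI * t / (period / ultradian_divisor))
    slow = amplitude * np.cos(_TWO_PI * t / period)
    v = mesor + (1 - frac) * fast + frac * slow
    return TimeSeries(v, dt, name="ultradian_morph")


def white_noise(duration: float, dt: float, sd: float = 1.0, seed: int = 0) -> TimeSeries:
    rng = np.random.default_rng(seed)
    t = _times(duration, dt)
    return TimeSeries(rng.normal(0.0, sd, t.size), dt, name="white_noise")


def pink_noise(duration: float, dt: float, sd: float = 1.0, seed: int = 0) -> TimeSeries:
    """1/f noise via spectral shaping of white noise: power density scaled by
    1/f, so the log-log spectral slope is approximately -1."""
    rng = np.random.default_rng(seed)
    t = _times(duration, dt)
    n = t.size
    spec = np.fft.rfft(rng.normal(0.0, 1.0, n))
    freqs = np.fft.rfftfreq(n, d=dt)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    v = np.fft.irfft(spec * scale, n)
    v = v / v.std() * sd
    return TimeSeries(v, dt, name="pink_noise")


def poisson_counts(
    duration: float,
    dt: float,
    period: float,
    mesor: float = 10.0,
    amplitude: float = 8.0,
    seed: int = 0,
) -> TimeSeries:
    """Count-like activity: Poisson draws around a clipped sinusoidal rate."""
    rng = np.random.default_rng(seed)
    t = _times(duration, dt)
    rate = np.clip(mesor + amplitude * np.cos(_TWO_PI * t / period), 0.0, None)
    return TimeSeries(rng.poisson(rate).astype(float), dt, name="poisson_counts")


def add_noise(ts: TimeSeries, snr: float, amplitude: float, seed: int = 0) -> TimeSeries:
    """Add white Gaussian noise with sd = amplitude/snr."""
    if snr <= 0:
        raise ValidationError("snr must be > 0")
    rng = np.random.default_rng(seed)
    noisy = ts.values + rng.normal(0.0, amplitude / snr, ts.n)
    return ts.copy_with(noisy, name=f"{ts.name}+noise")


def generate(spec: SynthSpec) -> TimeSeries:
    """Dispatch on ``spec.kind``; deterministic for a fixed seed."""
    kw = dict(duration=spec.duration, dt=spec.dt)
    if spec.kind == "sinusoid":
        ts = sinusoid(period=spec.period, amplitude=spec.amplitude, mesor=spec.mesor, **kw)
    elif spec.kind == "square":
        ts = square_wave(
            period=spec.period, amplitude=spec.amplitude, mesor=spec.mesor, duty=spec.duty, **kw
        )
    elif spec.kind == "two_component":
        if spec.period2 is None:
            raise ValidationError("two_component needs period2")
        ts = two_component(
            period1=spec.period,
            period2=spec.period2,
            amplitude1=spec.amplitude,
            amplitude2=spec.amplitude if spec.amplitude2 is None else spec.amplitude2,
            mesor=spec.mesor,
            **kw,
        )
    elif spec.kind == "phase_program":
        ts = phase_program(
            period=spec.period,
            schedule=spec.schedule,
            amplitude=spec.amplitude,
            mesor=spec.mesor,
            **kw,
        )
    elif spec.kind == "period_program":
        ts = period_program(
            schedule=spec.schedule, amplitude=spec.amplitude, mesor=spec.mesor, **kw
        )
    elif spec.kind == "shape_morph":
        ts = shape_morph(period=spec.period, amplitude=spec.amplitude, mesor=spec.mesor, **kw)
    elif spec.kind == "ultradian_morph":
        ts = ultradian_morph(
            period=spec.period, amplitude=spec.amplitude, mesor=spec.mesor, **kw
        )
    elif spec.kind == "white_noise":
        ts = white_noise(sd=spec.amplitude, seed=spec.seed, **kw)
    elif spec.kind == "pink_noise":
        ts = pink_noise(sd=spec.amplitude, seed=spec.seed, **kw)
    else:  # poisson_counts
        ts = poisson_counts(
            period=spec.period, mesor=spec.mesor, amplitude=spec.amplitude, seed=spec.seed, **kw
        )
    if spec.snr is not None and spec.kind not in ("white_noise", "pink_noise", "poisson_counts"):
        ts = add_noise(ts, spec.snr, spec.amplitude, seed=spec.seed)
    return ts
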