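"""Continuous wavelet-style convolution with a Gaussian-modulated sinusoid
for per-cycle phase markers, plus the Rayleigh homogeneity test for group
phase data.

The kernel is an odd (sine) wave under an even Gaussian envelope, so it sums
exactly to zero: the convolution g(t) ignores additive constants and linear
trends in the input.  After smoothing, upward threshold crossings of g(t)
mark onsets, local maxima the cycle middles and downward crossings the
offsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import TimeSeries, ValidationError
from .filters import moving_average

__all__ = [
    "WaveletKernel",
    "MarkerSet",
    "RayleighResult",
    "make_wavelet",
    "wavelet_convolve",
    "phase_markers",
    "rayleigh_r",
    "rayleigh_r_crit",
    "scalogram",
]

logger = logging.getLogger("serialrhythm")

_TWO_PI = 2.0 * np.pi


@dataclass
class WaveletKernel:
    period_T: float  # samples
    support_cycles: int
    values: np.ndarray
    gaussian_sigma: float  # samples

    @property
    def length(self) -> int:
        return int(self.values.size)

    @property
    def center(self) -> int:
        return (self.length - 1) // 2


@dataclass
class MarkerSet:
    """Per-cycle onset/middle/offset positions, in samples from the series
    origin (convert to wall time by multiplying by dt)."""

    onsets: np.ndarray
    middles: np.ndarray
    offsets: np.ndarray
    g: np.ndarray
    edge_width: int
    flags: list[str] = field(default_factory=list)

    @property
    def n_cycles(self) -> int:
        return int(self.onsets.size)


@dataclass
class RayleighResult:
    r: float
    v: int
    r_crit: float
    significant: bool
    mean_angle: float


def make_wavelet(
    T: float, support_cycles: int = 3, sigma: float | None = None
) -> WaveletKernel:
    """Sine wave of period T samples under a Gaussian envelope spanning
    ``support_cycles`` full cycles (length odd-adjusted so the kernel has an
    exact center).  sigma defaults to support/6, putting ~3 sigma at each
    edge.  Odd symmetry about the center makes the kernel sum exactly zero.
    """
    if T < 4:
        raise ValidationError("wavelet period must be at least 4 samples")
    if support_cycles < 1:
        raise ValidationError("support must cover at least one cycle")
    length = int(round(support_cycles * T))
    if length % 2 == 0:
        length += 1
    if sigma is None:
        sigma = length / 6.0
    tc = (length - 1) / 2.0
    t = np.arange(length, dtype=float)
    u = t - tc
    w = np.sin(_TWO_PI * u / T) * np.exp(-(u**2) / (2.0 * sigma**2))
    # vanishing first moment (project out the linear ramp, itself odd): the
    # convolution then annihilates linear trends as well as constants, while
    # the kernel stays exactly antisymmetric and zero-sum
    w -= (u @ w) / (u @ u) * u
    return WaveletKernel(
        period_T=float(T), support_cycles=support_cycles, values=w, gaussian_sigma=sigma
    )


def wavelet_convolve(
    ts, kernel: WaveletKernel, smooth_window: int | None = None
) -> tuple[np.ndarray, int]:
    """Convolve the series with the kernel and smooth the result.

    Returns (g, edge_width): g is aligned so that for a symmetric activity
    bout the upward threshold crossing of g falls at the bout onset, the
    maximum at its middle and the downward crossing at its end.  Because the
    kernel is odd, the raw sliding product is in quadrature with the input
    pattern; a quarter-cycle realignment restores the marker semantics.
    The first/last ``edge_width`` samples are contaminated by the series
    ends and should be ignored.  The smoothing window defaults to ~T/6,
    odd-adjusted.
    """
    x = ts.values if isinstance(ts, TimeSeries) else np.asarray(ts, dtype=float)
    if x.size <= kernel.length:
        raise ValidationError(
            f"series ({x.size} samples) must be longer than the kernel ({kernel.length})"
        )
    if np.any(np.isnan(x)):
        raise ValidationError("wavelet convolution requires a complete series")
    raw = np.correlate(x, kernel.values, mode="same")
    quarter = int(round(kernel.period_T / 4.0))
    g = np.empty_like(raw)
    g[quarter:] = raw[: raw.size - quarter]
    g[:quarter] = raw[0]
    if smooth_window is None:
        smooth_window = max(3, int(round(kernel.period_T / 6.0)) | 1)
    half = max(1, (int(smooth_window) - 1) // 2)
    if 2 * half + 1 <= g.size:
        g = moving_average(g, half)
    edge = kernel.length // 2 + quarter + half
    return g, edge


def phase_markers(
    g: np.ndarray,
    T: float,
    threshold: float = 0.0,
    edge_width: int = 0,
    refractory: float | None = None,
) -> MarkerSet:
    """Extract per-cycle onset / middle / offset markers from smoothed g(t).

    Onsets are upward crossings of the threshold; crossings within
    ``refractory`` samples (default T/4) of the previous onset are treated
    as noise and suppressed, allowing at most one onset per cycle.  The
    middle of each cycle is the maximum of g between consecutive onsets and
    the offset the first downward crossing after the middle.
    """
    g = np.asarray(g, dtype=float)
    if refractory is None:
        refractory = T / 4.0
    lo, hi = edge_width, g.size - edge_width
    prev, curr = g[:-1], g[1:]
    ups = np.nonzero((prev < threshold) & (curr >= threshold))[0] + 1
    ups = ups[(ups >= lo) & (ups < hi)]
    onsets: list[int] = []
    for u in ups:
        if onsets and u - onsets[-1] < refractory:
            continue
        onsets.append(int(u))
    if not onsets:
        return MarkerSet(
            onsets=np.array([]),
            middles=np.array([]),
            offsets=np.array([]),
            g=g,
            edge_width=edge_width,
            flags=["no_crossings"],
        )
    downs = np.nonzero((prev >= threshold) & (curr < threshold))[0] + 1
    middles = []
    offsets = []
    bounds = onsets + [min(hi, onsets[-1] + int(round(T)) + 1)]
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = g[a:b]
        middles.append(a + int(np.argmax(seg)))
        after = downs[(downs > middles[-1]) & (downs < b)]
        offsets.append(int(after[0]) if after.size else np.nan)
    return MarkerSet(
        onsets=np.asarray(onsets, dtype=float),
        middles=np.asarray(middles, dtype=float),
        offsets=np.asarray(offsets, dtype=float),
        g=g,
        edge_width=edge_width,
    )


def rayleigh_r_crit(v: int, p: float = 0.05) -> float:
    """Critical mean vector length at p = 0.05: r = 1.6732268 / v^0.492018."""
    if v < 2:
        raise ValidationError("Rayleigh test needs at least two cases")
    if abs(p - 0.05) > 1e-12:
        raise ValidationError("the critical-value formula is tabulated for p = 0.05 only")
    return 1.6732268 / v**0.492018


def rayleigh_r(angles) -> RayleighResult:
    """Rayleigh homogeneity test for a group of phase angles (radians).

    r is the modulus of the mean of the unit vectors (cos th_i, sin th_i);
    phases are significantly clustered at p = 0.05 when r exceeds the
    tabulated critical value.
    """
    th = np.asarray(angles, dtype=float)
    th = th[~np.isnan(th)]
    v = th.size
    if v < 2:
        raise ValidationError("Rayleigh test needs at least two cases")
    a = np.cos(th).mean()
    b = np.sin(th).mean()
    r = float(np.hypot(a, b))
    crit = rayleigh_r_crit(v)
    return RayleighResult(
        r=r,
        v=v,
        r_crit=crit,
        significant=r > crit,
        mean_angle=float(np.arctan2(b, a) % _TWO_PI),
    )


def scalogram(
    ts: TimeSeries, periods, support_cycles: int = 3, smooth_window: int | None = None
) -> np.ndarray:
    """Optional period scan: one convolution row per tested period (samples).
    Marker extraction still uses a single user-selected period."""
    rows = []
    for T in np.asarray(periods, dtype=float):
        kern = make_wavelet(T, support_cycles)
        g, _ = wavelet_convolve(ts, kern, smooth_window)
        rows.append(g)
    return np.vstack(rows)
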