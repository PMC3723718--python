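"""Simple low-pass pre-filters (moving average / moving median), the moving
average's analytic transfer function, normalized-frequency conversions and
series dichotomization.

Frequencies are normalized so that f = 1 is the Nyquist frequency (the
frequency corresponding to two sampling intervals): a period T in minutes
maps to f = 2*dt/T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import TimeSeries, ValidationError

__all__ = [
    "FilterSpec",
    "Dichotomizer",
    "moving_average",
    "moving_median",
    "transfer_function",
    "frequency_to_period",
    "period_to_frequency",
    "dichotomize",
]


@dataclass
class FilterSpec:
    """Half-window n; the full window is M = 2n + 1 samples."""

    half_window: int
    kind: str = "average"  # or "median"

    def __post_init__(self) -> None:
        if self.half_window < 1:
            raise ValidationError("half_window must be >= 1")
        if self.kind not in ("average", "median"):
            raise ValidationError(f"unknown filter kind {self.kind!r}")

    @property
    def window(self) -> int:
        return 2 * self.half_window + 1


def _as_array(x) -> tuple[np.ndarray, TimeSeries | None]:
    if isinstance(x, TimeSeries):
        return x.values, x
    return np.asarray(x, dtype=float), None


def _check_window(n: int, size: int) -> int:
    if n < 1:
        raise ValidationError("half-window must be >= 1")
    m = 2 * n + 1
    if m > size:
        raise ValidationError(f"window M={m} larger than series (N={size})")
    return m


def moving_average(ts, n: int):
    """Symmetric moving average over M = 2n+1 samples.

    Edges use the shrunken available window so the output keeps the input
    length and serial alignment.  Missing values are excluded from each
    window; a window with no present values yields NaN.
    """
    x, origin = _as_array(ts)
    _check_window(n, x.size)
    kernel = np.ones(2 * n + 1)
    present = ~np.isnan(x)
    filled = np.where(present, x, 0.0)
    num = np.convolve(filled, kernel, mode="same")
    den = np.convolve(present.astype(float), kernel, mode="same")
    out = np.full_like(x, np.nan)
    np.divide(num, den, out=out, where=den > 0)
    if origin is not None:
        return origin.copy_with(out)
    return out


def _lower_median(window: np.ndarray) -> float:
    """Median with the lower-median convention for even counts (edge windows
    and windows with excluded missing values)."""
    v = window[~np.isnan(window)]
    if v.size == 0:
        return np.nan
    v = np.sort(v)
    return float(v[(v.size - 1) // 2])


def moving_median(ts, n: int):
    """Running median over M = 2n+1 samples (shrinking at the edges).

    Highly effective at removing aberrant spikes while attenuating high
    frequencies comparably to a moving average of equal window.
    """
    x, origin = _as_array(ts)
    _check_window(n, x.size)
    size = x.size
    out = np.empty(size)
    for i in range(size):
        lo = max(0, i - n)
        hi = min(size, i + n + 1)
        out[i] = _lower_median(x[lo:hi])
    if origin is not None:
        return origin.copy_with(out)
    return out


def transfer_function(f, M: int):
    """Attenuation H(f) of the moving average of window M at normalized
    frequency f (f = 1 at Nyquist).

    H(f) = | sin(pi * f * M / 2) / (M * sin(pi * f / 2)) |, with H(0) = 1 by
    continuity.  The f/2 substitution converts the Nyquist-normalized f into
    cycles per sample, which is the variable of the underlying Dirichlet
    kernel; evaluated this way H matches the measured attenuation of
    sinusoids at every frequency, not just at the kernel's zeros.
    """
    if M < 1 or M % 2 == 0:
        raise ValidationError(f"window M must be odd and >= 1, got {M}")
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr < 0) or np.any(f_arr > 1):
        raise ValidationError("normalized frequency must lie in [0, 1]")
    nu = f_arr / 2.0  # cycles per sample
    denom = M * np.sin(np.pi * nu)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.abs(np.sin(np.pi * nu * M) / denom)
    h = np.where(f_arr == 0, 1.0, h)
    if np.isscalar(f) or f_arr.ndim == 0:
        return float(h)
    return h


def frequency_to_period(f: float, dt: float) -> float:
    """Period in minutes for normalized frequency f (f = 1 at Nyquist):
    T = 2*dt/f.  E.g. dt = 15 min, f = 0.4 -> 75 min."""
    if not (0 < f <= 1):
        raise ValidationError(f"normalized frequency must be in (0, 1], got {f}")
    if not (dt > 0):
        raise ValidationError("dt must be > 0")
    return 2.0 * dt / f


def period_to_frequency(T: float, dt: float) -> float:
    """Inverse of :func:`frequency_to_period`: f = 2*dt/T."""
    if not (T > 0):
        raise ValidationError("period must be > 0")
    if not (dt > 0):
        raise ValidationError("dt must be > 0")
    f = 2.0 * dt / T
    if f > 1 + 1e-12:
        raise ValidationError(
            f"period {T} is shorter than two sampling intervals (2*dt={2 * dt})"
        )
    return min(f, 1.0)


@dataclass
class Dichotomizer:
    """Resolve a threshold u from the data themselves (mean, median or a
    percentile) and map the series to {0, 1}."""

    threshold_kind: str = "median"
    percentile_q: float | None = None

    def __post_init__(self) -> None:
        if self.threshold_kind not in ("mean", "median", "percentile"):
            raise ValidationError(f"unknown threshold kind {self.threshold_kind!r}")
        if self.threshold_kind == "percentile":
            if self.percentile_q is None or not (0 < self.percentile_q < 100):
                raise ValidationError("percentile threshold needs q in (0, 100)")

    def resolve(self, y: np.ndarray) -> float:
        y = np.asarray(y, dtype=float)
        if y.size == 0 or np.all(np.isnan(y)):
            raise ValidationError("cannot resolve a threshold on an empty section")
        if self.threshold_kind == "mean":
            return float(np.nanmean(y))
        if self.threshold_kind == "median":
            return float(np.nanmedian(y))
        return float(np.nanpercentile(y, self.percentile_q))


def dichotomize(y, d: Dichotomizer | float) -> np.ndarray:
    """y' = 0 where y < u, 1 where y >= u.  ``d`` may be a Dichotomizer (u
    resolved from the section itself) or a fixed numeric threshold.  NaNs
    propagate."""
    arr = np.asarray(y, dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot dichotomize an empty section")
    u = d if isinstance(d, (int, float)) else d.resolve(arr)
    out = np.where(arr >= u, 1.0, 0.0)
    out[np.isnan(arr)] = np.nan
    return out
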