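"""Angular (within-cycle) estimators.

The acrophase is the angle of the best-fitting sinusoid; the circular
center of gravity places the samples on a unit circle weighted by their
values.  The two coincide exactly, which makes the acrophase the preferred
centrality marker even for non-sinusoidal patterns.  Flank (onset/offset)
detectors locate step-like transitions by correlation with Heaviside or
square-wave templates, or by threshold crossings on smoothed data.

Sample i (1-based, i = 1..n within the cycle) maps to angle 2*pi*i/n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import ValidationError
from .filters import Dichotomizer, dichotomize, moving_average

__all__ = [
    "PhaseEstimate",
    "FlankConfig",
    "FlankEstimate",
    "acrophase",
    "cog_linear",
    "cog_circular",
    "flank_heaviside",
    "flank_squarewave",
    "flank_threshold",
    "alpha_duration",
]

logger = logging.getLogger("serialrhythm")

_TWO_PI = 2.0 * np.pi


@dataclass
class PhaseEstimate:
    """An angle in [0, 2*pi) plus, for circular estimators, the center-of-
    gravity coordinates (a, b)."""

    angle: float
    a: float | None = None
    b: float | None = None
    flags: list[str] = field(default_factory=list)

    def time_in_cycle(self, period: float) -> float:
        """Map the angle to a time within a cycle of the given length."""
        return (self.angle % _TWO_PI) / _TWO_PI * period


@dataclass
class FlankConfig:
    method: str = "heaviside"
    dichotomize_first: bool = True
    threshold: Dichotomizer = field(default_factory=Dichotomizer)
    max_iterations: int = 25

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")


@dataclass
class FlankEstimate:
    """Onset (psi+) / offset (psi-) sample positions, 1-based within the
    cycle, with the correlation at the optimum."""

    onset: float | None = None
    offset: float | None = None
    fit_r: float = np.nan
    converged: bool = True
    iterations: int = 1

    def alpha(self, T: float) -> float:
        if self.onset is None or self.offset is None:
            return np.nan
        return (self.offset - self.onset) % T


def _clean(y) -> np.ndarray:
    arr = np.asarray(y, dtype=float)
    if arr.size < 2:
        raise ValidationError("section must contain at least two samples")
    return arr


def _trig_sums(arr: np.ndarray) -> tuple[float, float]:
    n = arr.size
    i = np.arange(1, n + 1)
    mask = ~np.isnan(arr)
    s = float(np.sum(arr[mask] * np.sin(_TWO_PI * i[mask] / n)))
    c = float(np.sum(arr[mask] * np.cos(_TWO_PI * i[mask] / n)))
    return s, c


def acrophase(y) -> PhaseEstimate:
    """Angle of the fitted sinusoid via the four-quadrant arctangent of
    (sum y_i sin(2*pi*i/n), sum y_i cos(2*pi*i/n)).

    For a sampled cosine peaking at sample i0 the result is 2*pi*i0/n.
    """
    arr = _clean(y)
    s, c = _trig_sums(arr)
    scale = np.nansum(np.abs(arr))
    if scale == 0 or np.hypot(s, c) < 1e-12 * max(scale, 1.0):
        raise ValidationError("undefined phase: zero resultant vector")
    return PhaseEstimate(angle=float(np.arctan2(s, c) % _TWO_PI))


def cog_linear(y) -> PhaseEstimate:
    """Mean time of events as an angle: phi = (2*pi/n) * sum(i*y_i)/sum(y_i).

    Not wrap-safe: a waveform that straddles the section boundary pulls the
    estimate into its trough.  Kept as the documented contrast to
    :func:`cog_circular`.
    """
    arr = _clean(y)
    flags = []
    if np.nanmin(arr) < 0:
        logger.warning("cog_linear fed negative values")
        flags.append("negative_values")
    total = np.nansum(arr)
    if total == 0:
        raise ValidationError("undefined center of gravity: sum of values is zero")
    n = arr.size
    i = np.arange(1, n + 1)
    mask = ~np.isnan(arr)
    phi = _TWO_PI / n * float(np.sum(i[mask] * arr[mask]) / total)
    return PhaseEstimate(angle=phi, flags=flags)


def cog_circular(y) -> PhaseEstimate:
    """Circular center of gravity: a = sum(y cos)/sum(y), b = sum(y sin)/sum(y).

    The angle of (a, b) equals the acrophase (the sums cancel in the
    tangent), independently of where the section starts within the cycle.
    """
    arr = _clean(y)
    flags = []
    if np.nanmin(arr) < 0:
        logger.warning("cog_circular fed negative values")
        flags.append("negative_values")
    total = np.nansum(arr)
    if total == 0:
        raise ValidationError("undefined center of gravity: sum of values is zero")
    s, c = _trig_sums(arr)
    a, b = c / total, s / total
    if np.hypot(a, b) < 1e-12:
        flags.append("undefined_angle")
        return PhaseEstimate(angle=np.nan, a=a, b=b, flags=flags)
    return PhaseEstimate(angle=float(np.arctan2(b, a) % _TWO_PI), a=a, b=b, flags=flags)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xd = x - x.mean()
    yd = y - y.mean()
    den = np.sqrt(np.sum(xd**2) * np.sum(yd**2))
    if den == 0:
        return np.nan
    return float(np.sum(xd * yd) / den)


def _prepare_flank_input(y, cfg: FlankConfig) -> np.ndarray:
    arr = _clean(y)
    if np.any(np.isnan(arr)):
        raise ValidationError("flank detection requires a complete section")
    if cfg.dichotomize_first and not np.all(np.isin(np.unique(arr), (0.0, 1.0))):
        arr = dichotomize(arr, cfg.threshold)
    if np.all(arr == arr[0]):
        raise ValidationError("constant section: flank correlation undefined")
    return arr


def flank_heaviside(y, cfg: FlankConfig | None = None, sign: str = "+") -> FlankEstimate:
    """Locate a single step by scanning a Heaviside template.

    The template is 0 before the displacement psi and 1 from psi to the end
    of the section (non-circular); sign "-" uses the complement.  The offset
    maximizing the Pearson correlation is returned 1-based (the first sample
    on the high/low side); ties break toward the smallest psi.
    """
    cfg = cfg or FlankConfig()
    if sign not in ("+", "-"):
        raise ValidationError("sign must be '+' or '-'")
    arr = _prepare_flank_input(y, cfg)
    n = arr.size
    if n < 4:
        raise ValidationError("section too short for flank detection (n >= 4)")
    best_c, best_r = None, -np.inf
    for c in range(1, n):
        template = np.zeros(n)
        template[c:] = 1.0
        if sign == "-":
            template = 1.0 - template
        r = _pearson(arr, template)
        if np.isnan(r):
            continue
        if r > best_r + 1e-15:
            best_c, best_r = c, r
    if best_c is None:
        raise ValidationError("flank correlation undefined on every offset")
    est = FlankEstimate(fit_r=best_r)
    if sign == "+":
        est.onset = float(best_c + 1)
    else:
        est.offset = float(best_c + 1)
    return est


def _square_template(n: int, c: int, d: int) -> np.ndarray:
    """Circular square wave: 1 on positions p with (p - c) mod n < (d - c) mod n."""
    p = np.arange(n)
    width = (d - c) % n
    return ((p - c) % n < width).astype(float)


def _best_given(arr: np.ndarray, n: int, fixed: int, vary_d: bool) -> tuple[int, float]:
    best, best_r = None, -np.inf
    for v in range(n):
        c, d = (fixed, v) if vary_d else (v, fixed)
        if (d - c) % n == 0:
            continue
        r = _pearson(arr, _square_template(n, c, d))
        if np.isnan(r):
            continue
        if r > best_r + 1e-15:
            best, best_r = v, r
    return best, best_r


def flank_squarewave(y, cfg: FlankConfig | None = None) -> FlankEstimate:
    """Joint onset/offset fit against a circular square-wave template.

    Starting from the Heaviside estimates (c = psi+, d = psi-), the offset d
    is re-fit holding c, then c holding d, repeating until the (c, d) pair
    repeats; a cap of ``max_iterations`` guards against oscillation, in
    which case the best-correlation pair seen is returned with
    ``converged=False``.
    """
    cfg = cfg or FlankConfig()
    arr = _prepare_flank_input(y, cfg)
    n = arr.size
    if n < 4:
        raise ValidationError("section too short for flank detection (n >= 4)")
    inner = FlankConfig(dichotomize_first=False, max_iterations=cfg.max_iterations)
    c = int(flank_heaviside(arr, inner, "+").onset) - 1
    d = int(flank_heaviside(arr, inner, "-").offset) - 1
    if (d - c) % n == 0:
        d = (c + n // 2) % n
    seen: list[tuple[int, int]] = [(c, d)]
    best_pair, best_r = (c, d), _pearson(arr, _square_template(n, c, d))
    converged = False
    iterations = 0
    for iterations in range(1, cfg.max_iterations + 1):
        d_new, _ = _best_given(arr, n, c, vary_d=True)
        c_new, r = _best_given(arr, n, d_new, vary_d=False)
        if r > best_r:
            best_pair, best_r = (c_new, d_new), r
        if (c_new, d_new) == (c, d):
            converged = True
            c, d = c_new, d_new
            break
        if (c_new, d_new) in seen:  # oscillating cycle
            break
        seen.append((c_new, d_new))
        c, d = c_new, d_new
    if converged:
        best_pair, best_r = (c, d), _pearson(arr, _square_template(n, c, d))
    return FlankEstimate(
        onset=float(best_pair[0] + 1),
        offset=float(best_pair[1] + 1),
        fit_r=best_r,
        converged=converged,
        iterations=iterations,
    )


def flank_threshold(
    y,
    cycle_T: float,
    mode: str = "crossing_up",
    threshold: Dichotomizer | float | None = None,
    smooth_window: int | None = None,
) -> float:
    """Simple markers for soft, noise-free waveforms.

    Crossing modes first smooth with a moving average of width close to one
    third of the cycle, then return the first 1-based sample where the
    series crosses the resolved threshold in the requested direction.
    ``min``/``max`` return the extremum position, ``max_increase`` /
    ``max_decrease`` the steepest transition.  Returns NaN (missing) when no
    crossing qualifies.
    """
    modes = ("crossing_up", "crossing_down", "min", "max", "max_increase", "max_decrease")
    if mode not in modes:
        raise ValidationError(f"unknown mode {mode!r}")
    arr = _clean(y)
    if mode in ("min", "max"):
        return float((np.nanargmin(arr) if mode == "min" else np.nanargmax(arr)) + 1)
    if mode in ("max_increase", "max_decrease"):
        d = np.diff(arr)
        idx = np.nanargmax(d) if mode == "max_increase" else np.nanargmin(d)
        return float(idx + 2)  # 1-based position of the later sample
    if smooth_window is None:
        smooth_window = max(3, int(round(cycle_T / 3)) | 1)
    half = max(1, (smooth_window - 1) // 2)
    smoothed = moving_average(arr, half) if 2 * half + 1 <= arr.size else arr
    thr = threshold if threshold is not None else Dichotomizer("mean")
    u = thr if isinstance(thr, (int, float)) else thr.resolve(smoothed)
    prev, curr = smoothed[:-1], smoothed[1:]
    if mode == "crossing_up":
        hits = np.nonzero((prev < u) & (curr >= u))[0]
    else:
        hits = np.nonzero((prev >= u) & (curr < u))[0]
    if hits.size == 0:
        logger.warning("no %s threshold crossing found", mode)
        return np.nan
    return float(hits[0] + 2)  # first qualifying sample, 1-based


def alpha_duration(flanks: FlankEstimate, T: float, dt_minutes: float | None = None):
    """Duration of the activity phase: (psi- - psi+) mod T, in samples;
    with ``dt_minutes`` also in hours and as percent of the cycle."""
    alpha = flanks.alpha(T)
    if dt_minutes is None:
        return alpha
    if np.isnan(alpha):
        return {"samples": np.nan, "hours": np.nan, "percent": np.nan}
    return {
        "samples": alpha,
        "hours": alpha * dt_minutes / 60.0,
        "percent": 100.0 * alpha / T,
    }
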