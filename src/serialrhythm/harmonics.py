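"""Least-squares harmonic decomposition per section, power spectra, the
serial-spectrum matrix and the two-close-periods linear model.

The model is y(t) = c0 + sum_i c_i cos(i*omega*t - theta_i), omega = 2*pi/T.
When the section length is an integer multiple of T the regressors are
orthogonal and the estimates coincide with discrete-Fourier coefficients;
otherwise ordinary least squares is still used but harmonic estimates are no
longer independent (a warning is logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import SectionSpec, TimeSeries, ValidationError, segment
from .filters import moving_average

__all__ = [
    "HarmonicSpectrum",
    "DualPeriodFit",
    "SerialSpectrum",
    "harmonic_fit",
    "power_spectrum",
    "serial_spectrum",
    "dual_period_fit",
]

logger = logging.getLogger("serialrhythm")

_TWO_PI = 2.0 * np.pi


@dataclass
class HarmonicSpectrum:
    mesor: float
    amplitudes: np.ndarray  # c_1 .. c_h
    phases: np.ndarray  # theta_1 .. theta_h, radians in [0, 2*pi)
    period_T: float  # samples
    orthogonal: bool = True

    @property
    def h(self) -> int:
        return int(self.amplitudes.size)

    @property
    def fundamental_omega(self) -> float:
        return _TWO_PI / self.period_T

    def harmonic_frequencies(self) -> np.ndarray:
        return np.arange(1, self.h + 1) * self.fundamental_omega


@dataclass
class DualPeriodFit:
    period_T1: float
    period_T2: float
    amplitudes: tuple[float, float]
    phases: tuple[float, float]
    mesor: float
    total_variance_fraction: float
    variance_fractions: tuple[float, float]
    ratio_T2: float


@dataclass
class SerialSpectrum:
    """Graphic-matrix payload: one row per section, one column per harmonic."""

    matrix: np.ndarray  # sections x harmonics, power fractions
    section_starts: np.ndarray
    spec: SectionSpec
    amplitudes: np.ndarray = field(default=None)


def _max_harmonics(T: float) -> int:
    return int(np.floor(T / 2.0))


def harmonic_fit(y, T: float, h: int | None = None) -> HarmonicSpectrum:
    """Fit h harmonics of period T (samples) by ordinary least squares on
    {1, cos(i*omega*t), sin(i*omega*t)}, t = 0..l-1.

    ``h`` defaults to min(12, floor(T/2)) and is capped at the within-cycle
    Nyquist limit.  A non-multiple section length triggers a warning: the
    harmonic estimates are then biased by each other (non-orthogonal).
    """
    arr = np.asarray(y, dtype=float)
    mask = ~np.isnan(arr)
    if mask.sum() < 3:
        raise ValidationError("harmonic fit needs at least three present samples")
    if not (T > 1):
        raise ValidationError("period T must exceed one sample")
    h_max = _max_harmonics(T)
    if h is None:
        h = min(12, h_max)
    if h < 1 or h > h_max:
        raise ValidationError(f"h must be in 1..{h_max} for T={T}, got {h}")
    l = arr.size
    ratio = l / T
    orthogonal = abs(ratio - round(ratio)) < 1e-9
    if not orthogonal:
        logger.warning(
            "section length %d is not a multiple of T=%g: harmonic estimates "
            "are not independent",
            l,
            T,
        )
    t = np.arange(l, dtype=float)
    omega = _TWO_PI / T
    cols = [np.ones(l)]
    for i in range(1, h + 1):
        cols.append(np.cos(i * omega * t))
        cols.append(np.sin(i * omega * t))
    design = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(design[mask], arr[mask], rcond=None)
    amps = np.hypot(beta[1::2], beta[2::2])
    phases = np.arctan2(beta[2::2], beta[1::2]) % _TWO_PI
    return HarmonicSpectrum(
        mesor=float(beta[0]),
        amplitudes=amps,
        phases=phases,
        period_T=float(T),
        orthogonal=orthogonal,
    )


def power_spectrum(spec: HarmonicSpectrum) -> np.ndarray:
    """Power fraction of each harmonic: p_i = c_i^2 / sum_j c_j^2."""
    sq = spec.amplitudes**2
    total = sq.sum()
    if total <= 1e-20 * (1.0 + spec.mesor**2):
        raise ValidationError("power spectrum undefined: all amplitudes are zero")
    return sq / total


def serial_spectrum(
    ts: TimeSeries,
    spec: SectionSpec,
    h: int | None = None,
    smooth_rows: int | None = None,
) -> SerialSpectrum:
    """Per-section power spectra as a sections x harmonics matrix.

    ``smooth_rows`` applies a vertical moving average (down each harmonic
    column) of that odd width to aid visualization of slow changes.
    """
    T = spec.period_T
    if h is None:
        h = min(12, _max_harmonics(T))
    sections = segment(ts, spec)
    matrix = np.full((len(sections), h), np.nan)
    amps = np.full((len(sections), h), np.nan)
    for row, sec in enumerate(sections):
        try:
            hs = harmonic_fit(sec.values, T, h)
            matrix[row] = power_spectrum(hs)
            amps[row] = hs.amplitudes
        except ValidationError:
            continue  # degenerate section stays NaN
    if smooth_rows is not None and smooth_rows > 1:
        half = max(1, (int(smooth_rows) - 1) // 2)
        if 2 * half + 1 <= matrix.shape[0]:
            matrix = np.column_stack(
                [moving_average(matrix[:, c], half) for c in range(matrix.shape[1])]
            )
    starts = np.array([s.start_offset * ts.dt for s in sections])
    return SerialSpectrum(matrix=matrix, section_starts=starts, spec=spec, amplitudes=amps)


def dual_period_fit(y, T1: float, T2: float) -> DualPeriodFit:
    """Joint least squares with sinusoids at two known, close periods.

    Because the regressors are not orthogonal for any finite section, the
    components are estimated simultaneously via the normal equations.  Each
    component's variance fraction is the variance of its fitted wave over
    the section divided by the section variance; ``ratio_T2`` is
    var(T2)/(var(T1)+var(T2)), the share of the second component.

    Sections must span at least two cycles of the longer period (three or
    more recommended; below three a warning is logged).
    """
    arr = np.asarray(y, dtype=float)
    mask = ~np.isnan(arr)
    if T1 == T2:
        raise ValidationError("the two periods must differ")
    l = arr.size
    t_max = max(T1, T2)
    if l < 2 * t_max:
        raise ValidationError(
            f"section ({l} samples) must span at least two cycles of T={t_max}"
        )
    if l < 3 * t_max:
        logger.warning("dual-period section spans fewer than three cycles of the longer period")
    t = np.arange(l, dtype=float)
    cols = [np.ones(l)]
    for T in (T1, T2):
        w = _TWO_PI / T
        cols.append(np.cos(w * t))
        cols.append(np.sin(w * t))
    design = np.column_stack(cols)[mask]
    cond = np.linalg.cond(design)
    if cond > 1e6:
        raise ValidationError(
            f"near-singular design (condition number {cond:.2e}): the two "
            "periods are too close for this section length"
        )
    yv = arr[mask]
    beta, *_ = np.linalg.lstsq(design, yv, rcond=None)
    comp1 = design[:, 1] * beta[1] + design[:, 2] * beta[2]
    comp2 = design[:, 3] * beta[3] + design[:, 4] * beta[4]
    fitted = beta[0] + comp1 + comp2
    total_var = np.var(yv)
    if total_var == 0:
        raise ValidationError("constant section: variance fractions undefined")
    resid_var = np.var(yv - fitted)
    v1, v2 = np.var(comp1), np.var(comp2)
    amps = (float(np.hypot(beta[1], beta[2])), float(np.hypot(beta[3], beta[4])))
    phs = (
        float(np.arctan2(beta[2], beta[1]) % _TWO_PI),
        float(np.arctan2(beta[4], beta[3]) % _TWO_PI),
    )
    return DualPeriodFit(
        period_T1=float(T1),
        period_T2=float(T2),
        amplitudes=amps,
        phases=phs,
        mesor=float(beta[0]),
        total_variance_fraction=float(1.0 - resid_var / total_var),
        variance_fractions=(float(v1 / total_var), float(v2 / total_var)),
        ratio_T2=float(v2 / (v1 + v2)) if (v1 + v2) > 0 else np.nan,
    )
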