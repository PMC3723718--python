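"""Per-section scalar descriptors and derived non-parametric indices:
intradaily variability (IV), relative amplitude (RA = (M10-L5)/(M10+L5))
and the entrainment fraction."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import (
    SectionSpec,
    SectionView,
    SerialResult,
    TimeSeries,
    ValidationError,
    serial_apply,
)

__all__ = [
    "ScalarStat",
    "NonparametricIndices",
    "serial_scalar",
    "intradaily_variability",
    "relative_amplitude",
    "entrainment_fraction",
]

logger = logging.getLogger("serialrhythm")

_STAT_KINDS = (
    "mean",
    "median",
    "percentile",
    "min",
    "max",
    "sum",
    "variance",
    "sd",
    "range",
)


@dataclass
class ScalarStat:
    """One of the simple per-section descriptors.

    ``variance``/``sd`` use the population convention (ddof=0) so that a
    sampled sinusoid of amplitude A over full cycles has variance exactly
    A^2/2.
    """

    kind: str = "mean"
    q: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _STAT_KINDS:
            raise ValidationError(f"unknown scalar stat {self.kind!r}")
        if self.kind == "percentile" and (self.q is None or not 0 < self.q < 100):
            raise ValidationError("percentile stat needs q in (0, 100)")

    @property
    def label(self) -> str:
        return f"p{self.q:g}" if self.kind == "percentile" else self.kind

    def compute(self, values: np.ndarray) -> float:
        v = np.asarray(values, dtype=float)
        v = v[~np.isnan(v)]
        if v.size == 0:
            return np.nan
        if self.kind == "mean":
            return float(np.mean(v))
        if self.kind == "median":
            return float(np.median(v))
        if self.kind == "percentile":
            return float(np.percentile(v, self.q))
        if self.kind == "min":
            return float(np.min(v))
        if self.kind == "max":
            return float(np.max(v))
        if self.kind == "sum":
            return float(np.sum(v))
        if self.kind == "variance":
            return float(np.var(v))
        if self.kind == "sd":
            return float(np.std(v))
        return float(np.max(v) - np.min(v))  # range


@dataclass
class NonparametricIndices:
    """RA and its building blocks (hour-scale means of the average daily
    profile); IV is attached when computed jointly."""

    RA: float
    M10: float
    L5: float
    IV: float | None = None


def serial_scalar(
    ts: TimeSeries,
    spec: SectionSpec,
    stat: ScalarStat,
    max_missing_fraction: float = 0.2,
) -> SerialResult:
    """Serial application of a scalar statistic (mesor, P95, SD, ...).

    Warns when the section length is not a multiple of the analysis period:
    in that case the Z series shows a residual oscillation at the period of
    the underlying rhythm rather than the true evolution of the statistic.
    """
    return serial_apply(
        ts,
        spec,
        lambda sec: stat.compute(sec.values),
        stat_name=stat.label,
        max_missing_fraction=max_missing_fraction,
    )


def _hourly_aggregate(y: np.ndarray, dt_minutes: float) -> np.ndarray:
    per_hour = int(round(60.0 / dt_minutes))
    if per_hour <= 1:
        return y
    n_full = (y.size // per_hour) * per_hour
    return np.nanmean(y[:n_full].reshape(-1, per_hour), axis=1)


def intradaily_variability(
    y, dt_minutes: float = 60.0, aggregate_hourly: bool = True
) -> float:
    """Fragmentation index based on hour-to-hour transitions.

    IV = [N * sum_{i=2..N} (y_i - y_{i-1})^2] / [(N-1) * sum (y_i - ybar)^2]

    The formula assumes hourly sampling; finer-resolution input is first
    aggregated to hourly means (disable with ``aggregate_hourly=False``,
    which logs a warning).  A maximally alternating series gives IV = 4, a
    smooth rhythm a value near 0.
    """
    arr = np.asarray(y, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        raise ValidationError("IV needs at least two values")
    if dt_minutes < 60.0:
        if aggregate_hourly:
            arr = _hourly_aggregate(arr, dt_minutes)
        else:
            logger.warning(
                "computing IV at native resolution dt=%g min; the index is "
                "defined for hourly data",
                dt_minutes,
            )
    n = arr.size
    denom = np.sum((arr - arr.mean()) ** 2)
    if denom == 0:
        raise ValidationError("IV undefined for a constant series")
    num = np.sum(np.diff(arr) ** 2)
    return float(n * num / ((n - 1) * denom))


def average_profile(
    y: np.ndarray, bins_per_cycle: int, use_median: bool = False
) -> np.ndarray:
    """Fold a section into complete cycles and average bin-wise."""
    arr = np.asarray(y, dtype=float)
    n_cycles = arr.size // bins_per_cycle
    if n_cycles < 1:
        raise ValidationError("section shorter than one cycle")
    folded = arr[: n_cycles * bins_per_cycle].reshape(n_cycles, bins_per_cycle)
    if use_median:
        return np.nanmedian(folded, axis=0)
    return np.nanmean(folded, axis=0)


def _best_circular_window(profile: np.ndarray, width: int, minimize: bool) -> tuple[int, float]:
    """Exhaustive search over circular window starts; earliest start wins on
    ties.  Returns (start_bin, window_mean)."""
    n = profile.size
    ext = np.concatenate([profile, profile[: width - 1]])
    means = np.array([np.nanmean(ext[i : i + width]) for i in range(n)])
    idx = int(np.nanargmin(means) if minimize else np.nanargmax(means))
    return idx, float(means[idx])


def relative_amplitude(
    ts: TimeSeries,
    cycle_minutes: float = 1440.0,
    use_median: bool = False,
    with_iv: bool = False,
) -> NonparametricIndices:
    """RA = (M10 - L5)/(M10 + L5) from the average daily profile.

    M10 / L5 are the mean levels of the most active 10 h and least active
    5 h circular windows of the profile, found by exhaustive search over all
    bin-aligned placements.  Sections should span 5 or more cycles for a
    stable profile (a warning is logged otherwise).
    """
    bins = int(round(cycle_minutes / ts.dt))
    if ts.n < 5 * bins:
        logger.warning(
            "RA computed on %.1f cycles; 5 or more are recommended", ts.n / bins
        )
    if np.nanmin(ts.values) < 0:
        logger.warning("RA expects nonnegative values")
    profile = average_profile(ts.values, bins, use_median=use_median)
    m10_w = max(1, int(round(600.0 / ts.dt)))
    l5_w = max(1, int(round(300.0 / ts.dt)))
    _, m10 = _best_circular_window(profile, m10_w, minimize=False)
    _, l5 = _best_circular_window(profile, l5_w, minimize=True)
    if m10 + l5 == 0:
        raise ValidationError("RA undefined: M10 + L5 = 0 (all-zero profile)")
    iv = None
    if with_iv:
        iv = intradaily_variability(ts.values, dt_minutes=ts.dt)
    return NonparametricIndices(RA=float((m10 - l5) / (m10 + l5)), M10=m10, L5=l5, IV=iv)


def entrainment_fraction(ts: TimeSeries, T_light: int) -> SerialResult:
    """Per-cycle fraction of activity falling in the first half of each
    lighting cycle (sections with s = l = T_light).  All-zero cycles yield a
    flagged missing value."""
    spec = SectionSpec(length_l=int(T_light), step_s=int(T_light), period_T=float(T_light))

    def stat(sec: SectionView) -> float:
        v = sec.values
        total = np.nansum(v)
        if total == 0:
            return np.nan
        half = sec.length // 2
        return float(np.nansum(v[:half]) / total)

    res = serial_apply(ts, spec, stat, stat_name="entrainment_fraction")
    res.flags = [
        ("all_zero_section" if np.isnan(v) and not f else f)
        for v, f in zip(res.values, res.flags)
    ]
    return res
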