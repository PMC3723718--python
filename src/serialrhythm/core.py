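"""Time-series container, section segmentation and serial-analysis driver.

A long record ``x_1 .. x_N`` (constant sampling interval ``dt``) is cut into
overlapping or non-overlapping sections of length ``l`` samples, displaced by
a step of ``s`` samples, and a per-section statistic produces the derived
series ``z_1 .. z_n`` whose evolution over time is the object of the serial
analysis.  Everything downstream (filters, phase estimators, harmonic
spectra, periodograms, wavelet markers) is driven through :func:`serial_apply`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "TimeSeries",
    "SectionSpec",
    "SectionView",
    "SerialResult",
    "MultiplicityCorrection",
    "PhaseTrackConfig",
    "segment",
    "sidak_per_test",
    "bonferroni_per_test",
    "effective_multiplicity",
    "track_phase",
    "serial_apply",
]

logger = logging.getLogger("serialrhythm")


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


@dataclass
class TimeSeries:
    """A uniformly sampled univariate series.

    Parameters
    ----------
    values : array-like
        The sample values.  ``NaN`` marks a missing observation.
    dt : float
        Sampling interval in minutes (must be > 0).
    start_time : float, optional
        Wall-clock origin of the first sample, in minutes.
    name : str
        Free-text label for reports and plots.
    """

    values: np.ndarray
    dt: float
    start_time: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("values must be one-dimensional")
        if self.values.size < 1:
            raise ValidationError("series must contain at least one sample")
        if not (self.dt > 0):
            raise ValidationError(f"dt must be > 0, got {self.dt}")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    @property
    def nyquist_frequency(self) -> float:
        """f_N = 1/(2*dt); the shortest analyzable period is 2*dt."""
        return 1.0 / (2.0 * self.dt)

    @property
    def times(self) -> np.ndarray:
        """Sample times in minutes relative to the series origin."""
        t0 = 0.0 if self.start_time is None else float(self.start_time)
        return t0 + self.dt * np.arange(self.n)

    @property
    def duration(self) -> float:
        """Total span covered by the samples, in minutes."""
        return self.n * self.dt

    def copy_with(self, values: np.ndarray, name: str | None = None) -> "TimeSeries":
        return TimeSeries(
            values=np.asarray(values, dtype=float),
            dt=self.dt,
            start_time=self.start_time,
            name=self.name if name is None else name,
        )


@dataclass
class SectionSpec:
    """Segmentation rule: section length ``l``, step ``s`` (samples) and the
    analysis period ``T`` (samples, may be fractional)."""

    length_l: int
    step_s: int
    period_T: float

    def __post_init__(self) -> None:
        if int(self.length_l) != self.length_l or self.length_l < 1:
            raise ValidationError(f"length_l must be an integer >= 1, got {self.length_l}")
        if int(self.step_s) != self.step_s or self.step_s < 1:
            raise ValidationError(f"step_s must be an integer >= 1, got {self.step_s}")
        if not (self.period_T > 0):
            raise ValidationError(f"period_T must be > 0, got {self.period_T}")
        self.length_l = int(self.length_l)
        self.step_s = int(self.step_s)

    @property
    def length_warns(self) -> bool:
        """True when ``l`` is not an integer multiple of ``T``: the derived
        series then carries a spurious oscillation at period ``T``."""
        ratio = self.length_l / self.period_T
        return abs(ratio - round(ratio)) > 1e-9

    def n_sections(self, n_samples: int) -> int:
        if self.length_l > n_samples:
            raise ValidationError(
                f"series shorter than section (N={n_samples} < l={self.length_l})"
            )
        return (n_samples - self.length_l) // self.step_s + 1


@dataclass
class SectionView:
    """One analysis window Y_j.

    ``index_j`` is 1-based (reporting convention); ``start_offset`` is the
    0-based sample offset (j-1)*s, i.e. the window covers 1-based samples
    (j-1)*s + 1 ... (j-1)*s + l.
    """

    index_j: int
    start_offset: int
    values: np.ndarray

    @property
    def length(self) -> int:
        return int(self.values.size)

    @property
    def missing_fraction(self) -> float:
        return float(np.isnan(self.values).mean())


@dataclass
class SerialResult:
    """The derived Z series: one value per section plus bookkeeping."""

    values: np.ndarray
    section_starts: np.ndarray  # real time units (minutes)
    stat_name: str
    spec: SectionSpec
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.section_starts = np.asarray(self.section_starts, dtype=float)
        if not self.flags:
            self.flags = [""] * self.values.size
        if len(self.flags) != self.values.size:
            raise ValidationError("flags must match values in length")

    @property
    def n_sections(self) -> int:
        return int(self.values.size)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "section_index": np.arange(1, self.n_sections + 1),
                "start_time": self.section_starts,
                "value": self.values,
                "flags": self.flags,
            }
        )


@dataclass
class MultiplicityCorrection:
    """Family-wise probability and the per-test level it maps to."""

    family_p: float
    m: int
    per_test_p: float


@dataclass
class PhaseTrackConfig:
    """Configuration for serial phase tracking/unwrapping.

    ``k`` preceding (already corrected) sections are used to extrapolate the
    expected phase of the next section by linear regression; the raw value is
    then shifted by whole cycles ``T`` to land within +/- T/2 of that
    expectation.
    """

    k: int = 3
    period_T: float = 24.0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError(f"k must be >= 1, got {self.k}")
        if not (self.period_T > 0):
            raise ValidationError("period_T must be > 0")


def segment(ts: TimeSeries, spec: SectionSpec) -> list[SectionView]:
    """Split ``ts`` into sections Y_j per the (l, s, T) rule.

    Returns exactly floor((N - l)/s) + 1 sections; section j covers 1-based
    samples (j-1)*s + 1 ... (j-1)*s + l and never extends past the series end.
    """
    n = spec.n_sections(ts.n)
    if spec.length_warns:
        logger.warning(
            "section length l=%d is not a multiple of the period T=%g; "
            "the Z series may carry a spurious oscillation at T",
            spec.length_l,
            spec.period_T,
        )
    out = []
    for j in range(1, n + 1):
        start = (j - 1) * spec.step_s
        out.append(
            SectionView(
                index_j=j,
                start_offset=start,
                values=ts.values[start : start + spec.length_l],
            )
        )
    return out


def iter_sections(ts: TimeSeries, spec: SectionSpec) -> Iterator[SectionView]:
    yield from segment(ts, spec)


def sidak_per_test(p: float, m: int) -> float:
    """Per-test significance level p_m = 1 - (1-p)^(1/m) that keeps the
    family-wise level at ``p`` across ``m`` tests."""
    if not (0.0 < p < 1.0):
        raise ValidationError(f"p must be in (0,1), got {p}")
    if m < 1:
        raise ValidationError(f"m must be >= 1, got {m}")
    return 1.0 - (1.0 - p) ** (1.0 / m)


def bonferroni_per_test(p: float, m: int) -> float:
    """Conservative companion p/m; approaches the Sidak value for m > 3."""
    if not (0.0 < p < 1.0):
        raise ValidationError(f"p must be in (0,1), got {p}")
    if m < 1:
        raise ValidationError(f"m must be >= 1, got {m}")
    return p / m


def effective_multiplicity(spec: SectionSpec) -> int:
    """Number of section-level tests sharing any one sample.

    With overlapping sections (s < l) a sample enters up to ceil(l/s)
    windows; with s >= l sections are disjoint and no correction is needed.
    """
    if spec.step_s >= spec.length_l:
        return 1
    return math.ceil(spec.length_l / spec.step_s)


def correction_for(spec: SectionSpec, family_p: float = 0.05) -> MultiplicityCorrection:
    m = effective_multiplicity(spec)
    return MultiplicityCorrection(
        family_p=family_p, m=m, per_test_p=sidak_per_test(family_p, m)
    )


def _extrapolate(prev: np.ndarray) -> float:
    """Least-squares linear extrapolation one step past ``prev``; with fewer
    than two points the expectation is simply the last value."""
    k = prev.size
    if k < 2:
        return float(prev[-1])
    x = np.arange(k, dtype=float)
    slope, intercept = np.polyfit(x, prev, 1)
    return float(intercept + slope * k)


def track_phase(
    raw_phases: Sequence[float], cfg: PhaseTrackConfig
) -> np.ndarray:
    """Wrap-correct a serial phase sequence.

    Each value is shifted by the integer multiple of ``T`` that brings it
    within +/- T/2 of the value extrapolated from the preceding (corrected)
    sections, so that no reported phase change exceeds half a cycle.  The
    first value passes through unchanged.  Missing values (NaN) are carried
    through and skipped in the extrapolation window.
    """
    raw = np.asarray(raw_phases, dtype=float)
    if raw.size == 0:
        raise ValidationError("track_phase needs at least one value")
    T = cfg.period_T
    corrected = np.empty_like(raw)
    corrected[0] = raw[0]
    history: list[float] = [] if np.isnan(raw[0]) else [raw[0]]
    for i in range(1, raw.size):
        if np.isnan(raw[i]):
            corrected[i] = np.nan
            continue
        if not history:
            corrected[i] = raw[i]
            history.append(raw[i])
            continue
        prev = np.asarray(history[-cfg.k :], dtype=float)
        expected = _extrapolate(prev)
        n_cycles = round((expected - raw[i]) / T)
        corrected[i] = raw[i] + n_cycles * T
        history.append(corrected[i])
    return corrected


def wrap_phase_change(raw_change: float, T: float, expected_change: float = 0.0) -> float:
    """Minimal-magnitude equivalent of a raw phase change within a cycle T.

    A computed shift of 18 h in a 24 h cycle is reported as -6 h: the value
    is moved by whole cycles until within +/- T/2 of the expected change.
    """
    n_cycles = round((expected_change - raw_change) / T)
    return raw_change + n_cycles * T


def serial_apply(
    ts: TimeSeries,
    spec: SectionSpec,
    section_statistic: Callable[[SectionView], float],
    stat_name: str = "stat",
    max_missing_fraction: float = 0.2,
) -> SerialResult:
    """Apply a per-section statistic to every section, yielding the Z series.

    Sections whose missing fraction exceeds ``max_missing_fraction`` yield
    NaN with a ``"too_missing"`` flag instead of a number.  Statistic errors
    are re-raised annotated with the 1-based section index.
    """
    sections = segment(ts, spec)
    values = np.empty(len(sections))
    flags = [""] * len(sections)
    for idx, sec in enumerate(sections):
        mf = sec.missing_fraction
        if mf > max_missing_fraction:
            values[idx] = np.nan
            flags[idx] = "too_missing"
            continue
        try:
            values[idx] = float(section_statistic(sec))
        except ValidationError:
            raise
        except Exception as exc:  # annotate with the failing section
            raise RuntimeError(f"statistic failed on section {sec.index_j}: {exc}") from exc
        if mf > 0:
            flags[idx] = f"missing_fraction={mf:.3f}"
    starts = np.array([s.start_offset * ts.dt for s in sections])
    if ts.start_time is not None:
        starts = starts + ts.start_time
    if spec.length_warns:
        flags = [f"{f};l_not_multiple_of_T" if f else "l_not_multiple_of_T" for f in flags]
    return SerialResult(
        values=values, section_starts=starts, stat_name=stat_name, spec=spec, flags=flags
    )
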