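"""Sokolove-Bushell and Lomb-Scargle periodograms (standard and generalized
floating-mean variants), significance thresholds, percent-variance scaling,
serial periodogram matrices and per-section peak tracking.

Every tested period is an independent test on the same data, so a
multiplicity correction across the period grid is applied when flagging
significance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import SectionSpec, TimeSeries, ValidationError, segment, sidak_per_test

__all__ = [
    "Periodogram",
    "PeakTrack",
    "SerialPeriodogram",
    "sokolove_bushell",
    "lomb_scargle",
    "lsp_threshold",
    "serial_periodogram",
    "peak_period",
]

logger = logging.getLogger("serialrhythm")

_TWO_PI = 2.0 * np.pi


@dataclass
class Periodogram:
    tested_periods: np.ndarray  # samples (SBP) or time units (LSP)
    statistic: np.ndarray
    percent_variance: np.ndarray
    method: str
    threshold: np.ndarray  # per-period statistic threshold at family-wise p
    significant: np.ndarray
    N: int
    K: np.ndarray | None = None  # complete cycles per tested period (SBP)


@dataclass
class PeakTrack:
    period: float
    statistic: float
    significant: bool


@dataclass
class SerialPeriodogram:
    matrix: np.ndarray  # sections x periods, method statistic
    percent_variance: np.ndarray
    section_starts: np.ndarray
    tested_periods: np.ndarray
    method: str
    peaks: list[PeakTrack] = field(default_factory=list)

    @property
    def peak_periods(self) -> np.ndarray:
        return np.array([p.period for p in self.peaks])


def sokolove_bushell(
    y,
    periods,
    alpha: float = 0.05,
    df_mode: str = "cycles",
    ragged: bool = False,
) -> Periodogram:
    """Chi-square type periodogram of a uniformly sampled series.

    For each integer tested period P the series is folded into K = floor(N/P)
    complete cycles (the trailing remainder is dropped unless
    ``ragged=True``), and

        Q_P = K * N' * sum_h (col_mean_h - mean)^2 / sum_j (y_j - mean)^2

    with N' the number of samples actually folded.  Percent variance is
    Q_P * 100 / N' (100% for a noise-free P-periodic signal).  Q_P is
    referred to a Chi^2 with df = K (``df_mode="cycles"``, as printed in the
    source method) or df = P - 1 (``df_mode="period"``, the usual literature
    convention); significance uses a Sidak correction across the grid.
    """
    arr = np.asarray(y, dtype=float)
    arr = arr[~np.isnan(arr)]
    n = arr.size
    periods = np.asarray(np.round(periods), dtype=int)
    if periods.size == 0:
        raise ValidationError("empty period grid")
    if np.any(periods < 2):
        raise ValidationError("tested periods must be >= 2 samples")
    if np.any(n // periods < 2):
        bad = periods[n // periods < 2]
        raise ValidationError(
            f"periods {bad.tolist()} leave fewer than two complete cycles in N={n}"
        )
    if df_mode not in ("cycles", "period"):
        raise ValidationError(f"unknown df_mode {df_mode!r}")
    q = np.empty(periods.size)
    pct = np.empty(periods.size)
    dfs = np.empty(periods.size)
    ks = np.empty(periods.size, dtype=int)
    for idx, P in enumerate(periods):
        K = n // P
        if ragged:
            yt = arr
            n_used = n
            col_means = np.array([arr[h::P].mean() for h in range(P)])
            counts = np.array([arr[h::P].size for h in range(P)])
            ybar = arr.mean()
            between = float(np.sum(counts * (col_means - ybar) ** 2)) / K
        else:
            n_used = K * P
            yt = arr[:n_used]
            ybar = yt.mean()
            col_means = yt.reshape(K, P).mean(axis=0)
            between = float(np.sum((col_means - ybar) ** 2))
        total = float(np.sum((yt - ybar) ** 2))
        if total == 0:
            raise ValidationError("constant series: periodogram undefined")
        q[idx] = K * n_used * between / total
        pct[idx] = q[idx] * 100.0 / n_used
        dfs[idx] = K if df_mode == "cycles" else P - 1
        ks[idx] = K
    per_test = sidak_per_test(alpha, periods.size) if periods.size > 1 else alpha
    thresh = stats.chi2.isf(per_test, dfs)
    return Periodogram(
        tested_periods=periods.astype(float),
        statistic=q,
        percent_variance=pct,
        method="sokolove_bushell",
        threshold=thresh,
        significant=q > thresh,
        N=n,
        K=ks,
    )


def _lsp_single(y: np.ndarray, t: np.ndarray, omega: float, floating: bool) -> float:
    n = y.size
    if floating:
        c0, s0 = np.cos(omega * t), np.sin(omega * t)
        num = np.sum(np.sin(2 * omega * t)) - 2.0 * c0.sum() * s0.sum() / n
        den = np.sum(np.cos(2 * omega * t)) - (c0.sum() ** 2 - s0.sum() ** 2) / n
        tau = np.arctan2(num, den) / (2.0 * omega)
        ct = np.cos(omega * (t - tau))
        st = np.sin(omega * (t - tau))
        cc = np.sum(ct**2) - ct.sum() ** 2 / n
        ss = np.sum(st**2) - st.sum() ** 2 / n
        cy = np.sum(y * ct) - y.sum() * ct.sum() / n
        sy = np.sum(y * st) - y.sum() * st.sum() / n
        yy = np.sum((y - y.mean()) ** 2)
        terms = 0.0
        if cc > 1e-12:
            terms += cy**2 / cc
        if ss > 1e-12:
            terms += sy**2 / ss
        return float(terms / yy)
    tau = np.arctan2(np.sum(np.sin(2 * omega * t)), np.sum(np.cos(2 * omega * t))) / (
        2.0 * omega
    )
    yd = y - y.mean()
    ct = np.cos(omega * (t - tau))
    st = np.sin(omega * (t - tau))
    cc = np.sum(ct**2)
    ss = np.sum(st**2)
    cy = np.sum(yd * ct)
    sy = np.sum(yd * st)
    f = 2.0 * np.var(y, ddof=1)
    terms = 0.0
    if cc > 1e-12:
        terms += cy**2 / cc
    if ss > 1e-12:
        terms += sy**2 / ss
    return float(terms / f)


def lomb_scargle(
    y,
    periods,
    times=None,
    dt: float = 1.0,
    floating: bool = False,
    alpha: float = 0.05,
    multiplicity: str = "N",
) -> Periodogram:
    """Lomb-Scargle periodogram P(omega), omega = 2*pi/T.

    The standard variant centers the data and normalizes by F = 2*var(y)
    (sample variance, ddof=1), so a noise-free sinusoid reaches (N-1)/2.
    The generalized floating-mean variant first standardizes the values to
    mean 0 / sd 1 and uses mean-corrected sums and the extended tau, so its
    maximum is 1 and 100*P reads as percent of explained variance.  Accepts
    explicit (possibly non-uniform) time stamps; otherwise times are
    i*dt.  ``multiplicity`` selects the Sidak-style exponent base for the
    significance threshold: "N" (as printed) or "n_tested" (the grid size).
    """
    arr = np.asarray(y, dtype=float)
    mask = ~np.isnan(arr)
    if times is None:
        times = np.arange(arr.size, dtype=float) * dt
    times = np.asarray(times, dtype=float)
    arr, times = arr[mask], times[mask]
    n = arr.size
    if n < 8:
        raise ValidationError("Lomb-Scargle needs at least 8 samples")
    if np.var(arr) == 0:
        raise ValidationError("constant series: periodogram undefined")
    periods = np.asarray(periods, dtype=float)
    span = times[-1] - times[0] + np.median(np.diff(times))
    min_p = 2.0 * np.median(np.diff(times))
    if np.any(periods < min_p - 1e-9) or np.any(periods > span + 1e-9):
        raise ValidationError(
            f"tested periods must lie within (2*dt={min_p:g}, N*dt={span:g})"
        )
    if floating:
        sd = np.std(arr, ddof=1)
        arr = (arr - arr.mean()) / sd
    p = np.array(
        [_lsp_single(arr, times, _TWO_PI / T, floating) for T in periods]
    )
    m = n if multiplicity == "N" else periods.size
    thr = lsp_threshold(n, alpha, floating=floating, n_tested=m)
    thresh = np.full(periods.size, thr)
    return Periodogram(
        tested_periods=periods,
        statistic=p,
        percent_variance=(100.0 * p if floating else p * 100.0 * 2.0 / (n - 1)),
        method="lomb_scargle_floating" if floating else "lomb_scargle",
        threshold=thresh,
        significant=p > thresh,
        N=n,
    )


def lsp_threshold(N: int, p: float, floating: bool = False, n_tested: int | None = None) -> float:
    """Significance threshold at family-wise level p, with the Sidak-style
    multiplicity exponent 1/m (m = N by default, per the printed formulas, or
    the number of tested periods via ``n_tested``).

    floating:  P_p = 1 - [1 - (1-p)^(1/m)]^(2/(N-3))
    standard:  P_p = ((N-2)/2) * {same bracket}
    """
    if N < 5:
        raise ValidationError("threshold needs N >= 5")
    if not (0 < p < 1):
        raise ValidationError(f"p must be in (0,1), got {p}")
    m = N if n_tested is None else int(n_tested)
    if m < 1:
        raise ValidationError("multiplicity must be >= 1")
    bracket = 1.0 - (1.0 - (1.0 - p) ** (1.0 / m)) ** (2.0 / (N - 3))
    if floating:
        return float(bracket)
    return float((N - 2) / 2.0 * bracket)


def peak_period(pgram: Periodogram) -> PeakTrack:
    """Argmax of the periodogram statistic; exact ties break toward the
    shorter period (the grid is scanned in ascending order)."""
    if pgram.tested_periods.size == 0:
        raise ValidationError("empty periodogram")
    order = np.argsort(pgram.tested_periods, kind="stable")
    stat = pgram.statistic[order]
    idx = int(np.nanargmax(stat))
    return PeakTrack(
        period=float(pgram.tested_periods[order][idx]),
        statistic=float(stat[idx]),
        significant=bool(pgram.significant[order][idx]),
    )


def serial_periodogram(
    ts: TimeSeries,
    spec: SectionSpec,
    periods,
    method: str = "lomb_scargle_floating",
    alpha: float = 0.05,
    normalize_rows: bool = False,
    **kwargs,
) -> SerialPeriodogram:
    """One periodogram per section plus the per-section peak track.

    Sections should encompass 8-10 cycles of the largest tested period for
    the Sokolove-Bushell variant (warned below 8; hard floor 2); the
    Lomb-Scargle variants are preferred for shorter sections.  Row
    normalization to a common maximum eases peak spotting but hides changes
    in rhythm strength.
    """
    periods = np.asarray(periods, dtype=float)
    largest = periods.max()
    if method == "sokolove_bushell":
        cycles = spec.length_l / largest
        if cycles < 2:
            raise ValidationError(
                "sections must span at least two cycles of the largest tested period"
            )
        if cycles < 8:
            logger.warning(
                "sections span %.1f cycles of the largest tested period; "
                "8-10 recommended for the Sokolove-Bushell periodogram (use "
                "Lomb-Scargle for shorter sections)",
                cycles,
            )
    sections = segment(ts, spec)
    matrix = np.full((len(sections), periods.size), np.nan)
    pct = np.full_like(matrix, np.nan)
    peaks: list[PeakTrack] = []
    for row, sec in enumerate(sections):
        if method == "sokolove_bushell":
            pg = sokolove_bushell(sec.values, periods, alpha=alpha, **kwargs)
        elif method in ("lomb_scargle", "lomb_scargle_floating"):
            pg = lomb_scargle(
                sec.values,
                periods * ts.dt,
                dt=ts.dt,
                floating=(method == "lomb_scargle_floating"),
                alpha=alpha,
                **kwargs,
            )
            pg.tested_periods = periods  # report in samples like SBP
        else:
            raise ValidationError(f"unknown periodogram method {method!r}")
        matrix[row] = pg.statistic
        pct[row] = pg.percent_variance
        peaks.append(peak_period(pg))
    if normalize_rows:
        row_max = np.nanmax(matrix, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            matrix = matrix / row_max
    starts = np.array([s.start_offset * ts.dt for s in sections])
    return SerialPeriodogram(
        matrix=matrix,
        percent_variance=pct,
        section_starts=starts,
        tested_periods=periods,
        method=method,
        peaks=peaks,
    )
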