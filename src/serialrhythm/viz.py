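"""Actogram and graphic-matrix rendering.

Actograms show one cycle per row (descending in time); double/triple
plotting repeats ``plot_factor`` consecutive cycles per row so drifting
phases stay readable.  Graphic matrices (serial spectra, serial
periodograms) are heatmaps with one row per section, optionally with a
peak-track overlay.  Every plot can dump its underlying array as CSV so
visual output stays numerically testable.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .core import SerialResult, TimeSeries, ValidationError

__all__ = ["actogram_matrix", "plot_actogram", "plot_matrix"]


def actogram_matrix(ts: TimeSeries, period_samples: int, plot_factor: int = 2) -> np.ndarray:
    """Fold a series into rows of ``plot_factor`` consecutive cycles.

    Row r shows cycles r .. r + plot_factor - 1; trailing samples that do
    not fill a complete cycle are padded with NaN.
    """
    if plot_factor not in (1, 2, 3):
        raise ValidationError("plot_factor must be 1, 2 or 3")
    p = int(period_samples)
    if p < 1:
        raise ValidationError("period must be at least one sample")
    n_rows = int(np.ceil(ts.n / p))
    padded = np.full(n_rows * p, np.nan)
    padded[: ts.n] = ts.values
    cycles = padded.reshape(n_rows, p)
    rows = []
    for r in range(n_rows):
        chunk = [cycles[r + k] if r + k < n_rows else np.full(p, np.nan) for k in range(plot_factor)]
        rows.append(np.concatenate(chunk))
    return np.vstack(rows)


def _dump_csv(arr: np.ndarray, path: Path) -> None:
    np.savetxt(path, arr, delimiter=",", fmt="%.17g")


def plot_actogram(
    ts: TimeSeries,
    period_samples: int,
    plot_factor: int = 2,
    overlays: dict[str, SerialResult] | None = None,
    path=None,
):
    """Render an actogram; phase-type overlays (values in samples within the
    cycle) are drawn at their within-cycle abscissa on each row."""
    mat = actogram_matrix(ts, period_samples, plot_factor)
    n_rows = mat.shape[0]
    fig, ax = plt.subplots(figsize=(8, max(2, 0.25 * n_rows)))
    finite = ts.values[~np.isnan(ts.values)]
    vmax = finite.max() if finite.size else 1.0
    vmin = finite.min() if finite.size else 0.0
    span = vmax - vmin if vmax > vmin else 1.0
    for r in range(n_rows):
        base = n_rows - r  # descending order: earliest cycle on top
        row = mat[r]
        x = np.arange(row.size)
        ax.fill_between(x, base, base + 0.8 * (row - vmin) / span, step="mid", color="k")
    if overlays:
        colors = plt.rcParams["axes.prop_cycle"].by_key()["color"]
        for ci, (label, res) in enumerate(overlays.items()):
            color = colors[ci % len(colors)]
            for j, v in enumerate(res.values):
                if np.isnan(v):
                    continue
                row = int(res.section_starts[j] / ts.dt // period_samples)
                if 0 <= row < n_rows:
                    ax.plot(v % period_samples, n_rows - row + 0.4, "o", ms=3, color=color)
            ax.plot([], [], "o", color=color, label=label)
        ax.legend(loc="upper right", fontsize=7)
    ax.set_xlim(0, period_samples * plot_factor)
    ax.set_ylim(0.5, n_rows + 1.5)
    ax.set_xlabel(f"time within {plot_factor} cycle(s) [samples]")
    ax.set_ylabel("cycle (descending)")
    ax.set_yticks([])
    if ts.name:
        ax.set_title(ts.name)
    if path is not None:
        path = Path(path)
        fig.savefig(path, dpi=120)
        fig.savefig(path.with_suffix(".svg"))
        _dump_csv(mat, path.with_suffix(".csv"))
        plt.close(fig)
    return fig, mat


def plot_matrix(
    matrix: np.ndarray,
    row_positions=None,
    col_positions=None,
    normalize_rows: bool = False,
    peak_track=None,
    xlabel: str = "column",
    ylabel: str = "section",
    cmap: str = "viridis",
    path=None,
):
    """Heatmap of a sections x columns matrix with optional per-row
    normalization (hides amplitude changes; off by default) and a
    peak-track overlay drawn at the per-row peak column position."""
    mat = np.asarray(matrix, dtype=float)
    if mat.ndim != 2:
        raise ValidationError("matrix must be two-dimensional")
    shown = mat.copy()
    if normalize_rows:
        with np.errstate(invalid="ignore", divide="ignore"):
            shown = shown / np.nanmax(shown, axis=1, keepdims=True)
    n_rows, n_cols = shown.shape
    x = np.arange(n_cols) if col_positions is None else np.asarray(col_positions, dtype=float)
    y = np.arange(n_rows) if row_positions is None else np.asarray(row_positions, dtype=float)
    fig, ax = plt.subplots(figsize=(7, max(2, 0.1 * n_rows)))
    im = ax.pcolormesh(x, y, shown, cmap=cmap, shading="nearest")
    fig.colorbar(im, ax=ax, shrink=0.8)
    if peak_track is not None:
        ax.plot(np.asarray(peak_track, dtype=float), y, color="red", lw=1.2)
    ax.invert_yaxis()  # earliest section on top, like an actogram
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    if path is not None:
        path = Path(path)
        fig.savefig(path, dpi=120)
        fig.savefig(path.with_suffix(".svg"))
        _dump_csv(mat, path.with_suffix(".csv"))
        plt.close(fig)
    return fig
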