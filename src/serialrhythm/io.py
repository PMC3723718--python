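"""Reading and writing series and serial results.

Supported series formats:

* ``csv_timestamp_value`` — comma-separated with a ``time,value`` header and
  ISO-8601 timestamps; the sampling interval is inferred and must be
  uniform (relative tolerance 1e-6).
* ``csv_value_only`` — one ``value`` column (header optional); the sampling
  interval must be declared.
* ``plain_text`` — one value per line; sampling interval declared.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .core import SerialResult, TimeSeries, ValidationError

__all__ = ["read_series", "write_series", "write_serial_result"]

_FORMATS = ("csv_timestamp_value", "csv_value_only", "plain_text")


def _sniff_format(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline().strip()
    if "," in first:
        head = first.lower().replace(" ", "")
        if head.startswith("time,") or "time" in head.split(","):
            return "csv_timestamp_value"
        return "csv_value_only"
    return "plain_text"


def _check_uniform(times_min: np.ndarray) -> float:
    diffs = np.diff(times_min)
    if diffs.size == 0:
        raise ValidationError("need at least two timestamps to infer dt")
    dt = float(np.median(diffs))
    if dt <= 0:
        raise ValidationError("timestamps must be strictly increasing")
    bad = np.nonzero(np.abs(diffs - dt) > 1e-6 * dt)[0]
    if bad.size:
        i = int(bad[0])
        raise ValidationError(
            f"non-uniform sampling: interval between rows {i + 1} and {i + 2} "
            f"is {diffs[i]:g} min (expected {dt:g} min)"
        )
    return dt


def read_series(path, fmt: str | None = None, dt: float | None = None) -> TimeSeries:
    """Read a series file; ``dt`` (minutes) is required for value-only and
    plain-text formats."""
    path = Path(path)
    fmt = fmt or _sniff_format(path)
    if fmt not in _FORMATS:
        raise ValidationError(f"unknown format {fmt!r}")
    if fmt == "csv_timestamp_value":
        df = pd.read_csv(path)
        cols = {c.lower().strip(): c for c in df.columns}
        if "time" not in cols or "value" not in cols:
            raise ValidationError("timestamped CSV needs 'time' and 'value' columns")
        try:
            stamps = pd.to_datetime(df[cols["time"]])
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"unparseable timestamps: {exc}") from exc
        minutes = (stamps - stamps.iloc[0]).dt.total_seconds().to_numpy() / 60.0
        dt_found = _check_uniform(minutes)
        values = pd.to_numeric(df[cols["value"]], errors="coerce").to_numpy(dtype=float)
        start = stamps.iloc[0].value / 1e9 / 60.0  # minutes since epoch
        return TimeSeries(values, dt_found, start_time=start, name=path.stem)
    if dt is None:
        raise ValidationError(f"format {fmt!r} requires an explicit dt")
    if fmt == "csv_value_only":
        rows: list[float] = []
        with open(path) as fh:
            for lineno, row in enumerate(csv.reader(fh), start=1):
                if not row or not row[0].strip():
                    continue
                cell = row[0].strip()
                if lineno == 1 and cell.lower() == "value":
                    continue
                try:
                    rows.append(float(cell))
                except ValueError as exc:
                    raise ValidationError(f"unparseable value at line {lineno}: {cell!r}") from exc
        return TimeSeries(np.array(rows), dt, name=path.stem)
    # plain text
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if lineno == 1 and line.lower() == "value":
                continue
            try:
                values.append(float(line))
            except ValueError as exc:
                raise ValidationError(f"unparseable value at line {lineno}: {line!r}") from exc
    return TimeSeries(np.array(values), dt, name=path.stem)


def write_series(ts: TimeSeries, path, fmt: str = "plain_text") -> None:
    """Write a series losslessly (17 significant digits)."""
    path = Path(path)
    if fmt == "csv_timestamp_value":
        t0 = 0.0 if ts.start_time is None else ts.start_time
        stamps = pd.to_datetime((t0 + ts.dt * np.arange(ts.n)) * 60.0, unit="s")
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["time", "value"])
            for s, v in zip(stamps, ts.values):
                writer.writerow([s.isoformat(), f"{v:.17g}"])
    elif fmt == "csv_value_only":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["value"])
            for v in ts.values:
                writer.writerow([f"{v:.17g}"])
    elif fmt == "plain_text":
        with open(path, "w") as fh:
            for v in ts.values:
                fh.write(f"{v:.17g}\n")
    else:
        raise ValidationError(f"unknown format {fmt!r}")


def write_serial_result(res: SerialResult, path) -> None:
    """Serialize a SerialResult to CSV with columns section_index,
    start_time, value, flags."""
    res.to_frame().to_csv(path, index=False, float_format="%.17g")
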