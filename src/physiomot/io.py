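"""Plain-text file formats.

All signals travel as comma-separated UTF-8 files with a header row and a
``t_sec`` time column (float seconds from local midnight of day 1):

* ``rr.csv``     — t_sec, rr_ms (beat annotations)
* ``counts.csv`` — t_sec, counts (epoch activity counts)
* ``acc.csv``    — t_sec, ax, ay, az (three-axis acceleration, g)
* ``sqi.csv``    — t_start_sec, channel, sqi (per-window per-channel quality)
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .signals import RRSeries, TimestampedSeries

__all__ = ["read_signal_csv", "write_series_csv"]

_KIND_COLUMNS = {
    "rr": ("t_sec", "rr_ms"),
    "counts": ("t_sec", "counts"),
    "series": ("t_sec", None),
    "acc": ("t_sec", "ax", "ay", "az"),
    "sqi": ("t_start_sec", "channel", "sqi"),
}


def _check_monotone(t: np.ndarray, path: Path) -> None:
    if len(t) > 1:
        bad = np.flatnonzero(np.diff(t) <= 0)
        if len(bad):
            line = int(bad[0]) + 3  # 1-based, +1 header, +1 next row
            raise ValueError(f"{path}: time not strictly increasing at line {line}")


def read_signal_csv(path: str | Path, kind: str):
    """Read and validate a typed signal file.

    ``kind`` is one of 'rr', 'counts', 'series' (any second column name),
    'acc' or 'sqi'. Raises with a line number on non-monotone time and
    names any missing column.
    """
    path = Path(path)
    if kind not in _KIND_COLUMNS:
        raise ValueError(f"unknown signal kind {kind!r}")
    df = pd.read_csv(path, comment="#")
    if len(df) == 0:
        raise ValueError(f"{path}: no samples")
    expected = _KIND_COLUMNS[kind]
    tcol = expected[0]
    for col in expected:
        if col is not None and col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if kind == "sqi":
        return df[["t_start_sec", "channel", "sqi"]].to_numpy(dtype=float)
    t = df[tcol].to_numpy(dtype=float)
    if kind != "acc":
        _check_monotone(t, path)
    if kind == "rr":
        return RRSeries(t, df["rr_ms"].to_numpy(dtype=float))
    if kind == "counts":
        return TimestampedSeries(t, df["counts"].to_numpy(dtype=float))
    if kind == "acc":
        _check_monotone(t, path)
        return {
            ax: TimestampedSeries(t, df[ax].to_numpy(dtype=float))
            for ax in ("ax", "ay", "az")
        }
    # generic series: t_sec + exactly one value column
    value_cols = [c for c in df.columns if c != tcol]
    if len(value_cols) != 1:
        raise ValueError(f"{path}: expected one value column, found {value_cols}")
    return TimestampedSeries(t, df[value_cols[0]].to_numpy(dtype=float))


def write_series_csv(
    path: str | Path,
    s: TimestampedSeries | RRSeries,
    value_name: str = "value",
    provenance: str | None = None,
) -> None:
    """Write a series with an optional ``#``-prefixed provenance header."""
    path = Path(path)
    if isinstance(s, RRSeries):
        t, v, value_name = s.beat_t, s.rr, "rr_ms"
    else:
        t, v = s.t, s.v
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        fh.write(f"t_sec,{value_name}\n")
        for ti, vi in zip(t, v):
            fh.write(f"{ti:.6f},{vi:.6f}\n")
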