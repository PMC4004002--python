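"""CSV readers/writers for signals and event lists.

Two small CSV dialects are used for interchange:

* signal files: header ``time_s,angular_velocity_dps``, one row per sample,
  uniformly spaced (validated against the declared sampling rate within
  1 µs);
* event files: header ``time_s,event,source`` with ``event`` in {IC, FO}
  and an optional extra ``subject`` column for grouped evaluation.

Writes are atomic (temp file + rename), so a failed command never leaves a
partial output file behind.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .events import EventSeries, GaitEvent
from .signal import GyroSignal

__all__ = [
    "FormatError",
    "read_signal",
    "write_signal",
    "read_events",
    "write_events",
]

SIGNAL_COLUMNS = ("time_s", "angular_velocity_dps")
EVENT_COLUMNS = ("time_s", "event", "source")
_SPACING_TOL_S = 1e-6


class FormatError(ValueError):
    """A file does not conform to the expected CSV dialect."""


def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc


def read_signal(path, fs: Optional[float] = None) -> GyroSignal:
    """Read a signal CSV; validate uniform spacing against ``fs``.

    If ``fs`` is not given it is inferred from the median sample spacing;
    either way every timestamp must match ``t0 + n/fs`` within 1e-6 s.
    """
    df = _read_csv(path)
    for col in SIGNAL_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    times = pd.to_numeric(df["time_s"], errors="coerce").to_numpy(dtype=float)
    values = pd.to_numeric(df["angular_velocity_dps"], errors="coerce").to_numpy(
        dtype=float
    )
    for name, arr in (("time_s", times), ("angular_velocity_dps", values)):
        bad = np.flatnonzero(~np.isfinite(arr))
        if bad.size:
            raise FormatError(
                f"{path}: non-numeric value in column {name!r} at row {bad[0] + 2}"
            )
    if len(times) == 0:
        return GyroSignal(np.zeros(0), fs=fs or 125.0)
    t0 = float(times[0])
    if fs is None:
        if len(times) < 2:
            raise FormatError(f"{path}: cannot infer sampling rate from one row")
        dt = float(np.median(np.diff(times)))
        if dt <= 0:
            raise FormatError(f"{path}: non-increasing timestamps")
        fs = 1.0 / dt
    expected = t0 + np.arange(len(times)) / fs
    err = np.abs(times - expected)
    bad = np.flatnonzero(err > _SPACING_TOL_S)
    if bad.size:
        raise FormatError(
            f"{path}: non-uniform sample spacing at row {bad[0] + 2} "
            f"(expected t={expected[bad[0]]:.6f}, got t={times[bad[0]]:.6f} "
            f"for fs={fs:g} Hz)"
        )
    return GyroSignal(values, fs=fs, t0=t0)


def write_signal(signal: GyroSignal, path) -> None:
    """Write a signal CSV (full float precision, atomic)."""
    df = pd.DataFrame(
        {"time_s": signal.times, "angular_velocity_dps": signal.samples}
    )
    _atomic_to_csv(df, path)


def read_events(path, fs: Optional[float] = None, t0: float = 0.0) -> EventSeries:
    """Read an event CSV into an :class:`EventSeries`.

    Event kinds must be IC or FO and times strictly increasing. Sample
    indices are reconstructed as ``round((t − t0) · fs)`` when ``fs`` is
    given, otherwise left as ``None``. A homogeneous ``source`` column sets
    the series label.
    """
    df = _read_csv(path)
    for col in ("time_s", "event"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    times = pd.to_numeric(df["time_s"], errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(times))
    if bad.size:
        raise FormatError(f"{path}: non-numeric time at row {bad[0] + 2}")
    kinds = df["event"].astype(str).str.strip().tolist()
    for i, kind in enumerate(kinds):
        if kind not in ("IC", "FO"):
            raise FormatError(f"{path}: unknown event kind {kind!r} at row {i + 2}")
    for i in range(1, len(times)):
        if times[i] <= times[i - 1]:
            raise FormatError(
                f"{path}: event times must be strictly increasing "
                f"(row {i + 2}: {times[i]} after {times[i - 1]})"
            )
    sources = (
        df["source"].astype(str).str.strip().tolist()
        if "source" in df.columns
        else []
    )
    label = sources[0] if sources and len(set(sources)) == 1 else "reference"
    events = [
        GaitEvent(
            kind,
            int(round((t - t0) * fs)) if fs is not None else None,
            float(t),
        )
        for kind, t in zip(kinds, times)
    ]
    return EventSeries(events, source=label)


def write_events(series: EventSeries, path) -> None:
    """Write an event CSV (atomic)."""
    df = pd.DataFrame(
        {
            "time_s": [e.time for e in series],
            "event": [e.kind for e in series],
            "source": [series.source] * len(series),
        }
    )
    _atomic_to_csv(df, path)


def read_event_table(path) -> pd.DataFrame:
    """Read an event CSV keeping all columns (e.g. a ``subject`` column)."""
    df = _read_csv(path)
    for col in ("time_s", "event"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    df = df.copy()
    df["time_s"] = pd.to_numeric(df["time_s"], errors="coerce")
    bad = np.flatnonzero(~np.isfinite(df["time_s"].to_numpy(dtype=float)))
    if bad.size:
        raise FormatError(f"{path}: non-numeric time at row {bad[0] + 2}")
    df["event"] = df["event"].astype(str).str.strip()
    unknown = ~df["event"].isin(["IC", "FO"])
    if unknown.any():
        row = int(np.flatnonzero(unknown.to_numpy())[0])
        raise FormatError(
            f"{path}: unknown event kind {df['event'].iloc[row]!r} at row {row + 2}"
        )
    return df


def _atomic_to_csv(df: pd.DataFrame, path) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(
        dir=path.parent or Path("."), prefix=f".{path.name}.", suffix=".tmp"
    )
    try:
        with os.fdopen(fd, "w", newline="") as fh:
            df.to_csv(fh, index=False)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
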