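"""Readers and writers for the on-disk formats.

Three formats are handled:

* Empatica-E4-style CSV signal exports — one directory per sleep session
  holding ``HR.csv``, ``TEMP.csv``, ``ACC.csv``, ``BVP.csv`` (first row =
  UTC start timestamp, second row = sampling rate in Hz, then samples; ACC
  has three columns) and ``IBI.csv`` (rows of ``offset_s, interval_s``).
* Self-report CSV — one row per session with bedtime/wake time (``HH:MM`` or
  minutes-since-midnight), latency, awakenings, Likert quality score and the
  scale maximum.
* Feature-matrix CSV — ``user_id, dataset_id, session_index, label`` followed
  by feature columns.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .types import (
    META_COLUMNS,
    DatasetTable,
    IbiSeries,
    RawSignal,
    SelfReport,
    SleepSession,
)

__all__ = [
    "FormatError",
    "read_e4_session",
    "write_e4_session",
    "read_selfreports",
    "read_feature_matrix",
    "write_feature_matrix",
]

#: E4 export files carrying uniformly sampled signals, with channel counts.
_E4_SIGNAL_FILES = {"HR.csv": 1, "TEMP.csv": 1, "BVP.csv": 1, "ACC.csv": 3}


class FormatError(ValueError):
    """A file does not follow its declared dialect."""


def _parse_e4_signal(path: Path, n_channels: int) -> RawSignal:
    try:
        raw = pd.read_csv(path, header=None)
    except Exception as exc:  # noqa: BLE001 - reported as a format error
        raise FormatError(f"{path.name}: cannot parse as CSV ({exc})") from exc
    if raw.shape[0] < 3:
        raise FormatError(f"{path.name}: empty data body (need header rows + samples)")
    try:
        start = float(raw.iloc[0, 0])
        rate = float(raw.iloc[1, 0])
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path.name}: malformed header rows") from exc
    if rate <= 0:
        raise FormatError(f"{path.name}: non-positive sampling rate {rate}")
    if raw.shape[1] < n_channels:
        raise FormatError(f"{path.name}: expected {n_channels} channels")
    body = raw.iloc[2:, :n_channels].apply(pd.to_numeric, errors="coerce")
    if body.isna().any().any():
        raise FormatError(f"{path.name}: non-numeric sample values")
    samples = body.to_numpy(dtype=float)
    if n_channels == 1:
        samples = samples[:, 0]
        channels = None
    else:
        channels = ["x", "y", "z"]
    return RawSignal(samples, sampling_rate=rate, start_time=start, channel_names=channels)


def _parse_ibi(path: Path) -> IbiSeries:
    try:
        raw = pd.read_csv(path, header=None)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{path.name}: cannot parse as CSV ({exc})") from exc
    # The device export puts the session start timestamp and the literal
    # token "IBI" in the first row; tolerate its presence or absence.
    first = raw.iloc[0].astype(str).str.strip()
    if first.str.contains("IBI", case=False).any():
        raw = raw.iloc[1:]
    if raw.empty:
        raise FormatError(f"{path.name}: empty data body")
    vals = raw.apply(pd.to_numeric, errors="coerce")
    if vals.shape[1] != 2 or vals.isna().any().any():
        raise FormatError(f"{path.name}: expected numeric (offset, interval) pairs")
    offsets = vals.iloc[:, 0].to_numpy(dtype=float)
    intervals_s = vals.iloc[:, 1].to_numpy(dtype=float)
    return IbiSeries(offsets=offsets, intervals=intervals_s * 1000.0)


def read_e4_session(
    dir_path: str | Path,
    wrist: str = "left",
    user_id: str = "unknown",
    dataset_id: str = "unknown",
    session_index: int = 0,
) -> SleepSession:
    """Read one session directory of E4-style CSV exports.

    If the directory contains a per-wrist subdirectory (``left``/``right``),
    the ``wrist`` flag selects which one to read; ``"unspecified"`` falls back
    to the directory itself. Missing files yield absent signal-map entries.
    """
    dir_path = Path(dir_path)
    if wrist not in ("left", "right", "unspecified"):
        raise ValueError(f"wrist must be left/right/unspecified, got {wrist!r}")
    if wrist != "unspecified" and (dir_path / wrist).is_dir():
        dir_path = dir_path / wrist
    if not dir_path.is_dir():
        raise FormatError(f"not a directory: {dir_path}")

    signals: dict[str, RawSignal | IbiSeries] = {}
    for fname, n_ch in _E4_SIGNAL_FILES.items():
        path = dir_path / fname
        if path.exists():
            signals[fname[:-4]] = _parse_e4_signal(path, n_ch)
    ibi_path = dir_path / "IBI.csv"
    if ibi_path.exists():
        signals["IBI"] = _parse_ibi(ibi_path)
    if not signals:
        raise FormatError(f"{dir_path}: no E4 signal files found")
    return SleepSession(
        user_id=user_id,
        dataset_id=dataset_id,
        session_index=session_index,
        signals=signals,
    )


def write_e4_session(session: SleepSession, dir_path: str | Path) -> None:
    """Write a session's signals back out in the E4 CSV dialect."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    name_map = {"HR": "HR.csv", "TEMP": "TEMP.csv", "BVP": "BVP.csv", "ACC": "ACC.csv"}
    for key, fname in name_map.items():
        sig = session.signals.get(key)
        if sig is None:
            continue
        assert isinstance(sig, RawSignal)
        samples = sig.samples if sig.samples.ndim == 2 else sig.samples[:, None]
        n_ch = samples.shape[1]
        header = np.full((2, n_ch), np.nan)
        header[0, :] = sig.start_time
        header[1, :] = sig.sampling_rate
        out = np.vstack([header, samples])
        pd.DataFrame(out).to_csv(dir_path / fname, header=False, index=False)
    ibi = session.signals.get("IBI")
    if ibi is not None:
        assert isinstance(ibi, IbiSeries)
        df = pd.DataFrame({"offset": ibi.offsets, "interval": ibi.intervals / 1000.0})
        df.to_csv(dir_path / "IBI.csv", header=False, index=False)


def _parse_clock(value) -> float:
    """Parse a clock time: ``HH:MM`` or minutes-since-midnight."""
    if isinstance(value, str) and ":" in value:
        hh, mm = value.strip().split(":")
        minutes = int(hh) * 60 + int(mm)
    else:
        minutes = float(value)
    return minutes % (24 * 60)


_REPORT_COLUMNS = [
    "user_id",
    "session_index",
    "bedtime",
    "wake_time",
    "latency",
    "awakenings",
    "quality_score",
]


def read_selfreports(
    csv_path: str | Path, scale_max: int | None = None
) -> list[tuple[str, int, SelfReport]]:
    """Read a self-report table; one record per valid row.

    Rows that violate the self-report invariants (e.g. a quality score above
    the scale maximum) are rejected; a single warning reports their row
    numbers. ``scale_max`` may come from a column or from the argument.
    """
    try:
        df = pd.read_csv(csv_path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{csv_path}: empty self-report file", stacklevel=2)
        return []
    if df.empty:
        warnings.warn(f"{csv_path}: empty self-report file", stacklevel=2)
        return []
    missing = [c for c in _REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{csv_path}: missing columns {missing}")
    if "scale_max" not in df.columns:
        if scale_max is None:
            raise FormatError(
                f"{csv_path}: no scale_max column and no scale_max argument"
            )
        df["scale_max"] = scale_max

    records: list[tuple[str, int, SelfReport]] = []
    rejected: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        try:
            report = SelfReport(
                bedtime=_parse_clock(row["bedtime"]),
                wake_time=_parse_clock(row["wake_time"]),
                latency=float(row["latency"]),
                awakenings=int(row["awakenings"]),
                quality_score=int(row["quality_score"]),
                scale_max=int(row["scale_max"]),
            )
        except (ValueError, TypeError) as exc:
            rejected.append((int(i) + 2, str(exc)))  # +2: header + 1-based
            continue
        records.append((str(row["user_id"]), int(row["session_index"]), report))
    if rejected:
        detail = "; ".join(f"row {r}: {msg}" for r, msg in rejected)
        warnings.warn(f"{csv_path}: rejected {len(rejected)} row(s): {detail}",
                      stacklevel=2)
    return records


def read_feature_matrix(csv_path: str | Path) -> DatasetTable:
    """Read a feature-matrix CSV into a :class:`DatasetTable`.

    Rows come back sorted by ``(user_id, session_index)``; duplicate pairs and
    a missing ``label`` column are errors.
    """
    df = pd.read_csv(csv_path)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{csv_path}: missing columns {missing}")
    df["user_id"] = df["user_id"].astype(str)
    df["dataset_id"] = df["dataset_id"].astype(str)
    return DatasetTable(df)


def write_feature_matrix(table: DatasetTable, csv_path: str | Path) -> None:
    """Write a feature matrix; numeric values keep full round-trip precision."""
    table.df.to_csv(csv_path, index=False, float_format="%.17g")
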