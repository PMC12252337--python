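"""Core domain types for wrist-wearable sleep-session analysis.

A *sleep session* is one participant's nightly sleep period: a bundle of raw
sensor signals (heart rate, inter-beat intervals, skin temperature,
acceleration, blood-volume pulse) plus a morning self-report. Feature
extraction turns a session into fixed-dimension per-modality feature vectors;
collections of labelled sessions form a :class:`DatasetTable`, the unit over
which covariate shift is diagnosed and models are evaluated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RawSignal",
    "IbiSeries",
    "SelfReport",
    "SleepSession",
    "FeatureVector",
    "LabelledExample",
    "DatasetTable",
    "MODALITY_DIMS",
    "META_COLUMNS",
    "HIGH",
    "LOW",
]

#: Binary sleep-quality labels.
HIGH = "high"
LOW = "low"

#: Fixed dimensionality of each modality's feature vector.
MODALITY_DIMS = {
    "HR": 12,
    "HRV": 19,
    "ST": 12,
    "ACC": 12,
    "RP": 12,
    "all-sensor-features": 67,
    "contextual": 4,
    "all-features": 71,
}

#: Metadata columns of a feature matrix, in canonical order.
META_COLUMNS = ["user_id", "dataset_id", "session_index", "label"]


@dataclass
class RawSignal:
    """A uniformly sampled sensor signal.

    ``samples`` is 1-D for single-channel signals or ``(n, c)`` for
    multi-channel signals (the accelerometer has three axes).
    """

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.samples.size == 0:
            raise ValueError("signal must contain at least one sample")
        if self.samples.ndim > 2:
            raise ValueError("samples must be 1-D or 2-D (n, channels)")
        if self.channel_names is not None and self.samples.ndim == 2:
            if len(self.channel_names) != self.samples.shape[1]:
                raise ValueError("channel_names length does not match channel count")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.n_samples / self.sampling_rate

    def magnitude(self) -> np.ndarray:
        """Collapse a multi-channel signal to its Euclidean magnitude."""
        if self.samples.ndim == 1:
            return self.samples
        return np.sqrt(np.sum(self.samples**2, axis=1))


@dataclass
class IbiSeries:
    """Inter-beat intervals: event offsets (s since session start) and
    interval durations in milliseconds."""

    offsets: np.ndarray
    intervals: np.ndarray

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.offsets.shape != self.intervals.shape or self.offsets.ndim != 1:
            raise ValueError("offsets and intervals must be equal-length 1-D arrays")
        if len(self.offsets) and np.any(np.diff(self.offsets) <= 0):
            raise ValueError("offsets must be strictly increasing")
        if np.any(self.intervals <= 0):
            raise ValueError("intervals must be positive")

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class SelfReport:
    """Morning self-report about the previous night.

    Times are minutes since midnight; a bedtime later than the wake time is
    interpreted as crossing midnight downstream.
    """

    bedtime: float
    wake_time: float
    latency: float
    awakenings: int
    quality_score: int
    scale_max: int

    def __post_init__(self) -> None:
        if not (1 <= self.quality_score <= self.scale_max):
            raise ValueError(
                f"quality_score {self.quality_score} outside [1, {self.scale_max}]"
            )
        if self.latency < 0:
            raise ValueError("latency must be >= 0")
        if self.awakenings < 0:
            raise ValueError("awakenings must be >= 0")
        for name in ("bedtime", "wake_time"):
            v = getattr(self, name)
            if not (0 <= v < 24 * 60):
                raise ValueError(f"{name} must be in [0, 1440) minutes, got {v}")


@dataclass
class SleepSession:
    """One night of raw signals and self-report for one user of one dataset."""

    user_id: str
    dataset_id: str
    session_index: int
    signals: dict[str, RawSignal | IbiSeries] = field(default_factory=dict)
    report: SelfReport | None = None

    def __post_init__(self) -> None:
        if not self.dataset_id:
            raise ValueError("dataset_id must be non-empty")


@dataclass
class FeatureVector:
    """Named per-modality feature values.

    For the canonical modalities the dimension is checked against
    :data:`MODALITY_DIMS`; other modality names (e.g. synthetic feature sets)
    may have any dimension.
    """

    modality: str
    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(self.values):
            raise ValueError("names and values must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        expected = MODALITY_DIMS.get(self.modality)
        if expected is not None and len(self.values) != expected:
            raise ValueError(
                f"modality {self.modality!r} requires {expected} features, "
                f"got {len(self.values)}"
            )

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class LabelledExample:
    """A feature vector with its binary sleep-quality label."""

    user_id: str
    dataset_id: str
    session_index: int
    features: FeatureVector
    label: str

    def __post_init__(self) -> None:
        if self.label not in (HIGH, LOW):
            raise ValueError(f"label must be {HIGH!r} or {LOW!r}, got {self.label!r}")


class DatasetTable:
    """A feature matrix for one dataset: rows are labelled sessions.

    Wraps a :class:`pandas.DataFrame` whose columns are
    ``user_id, dataset_id, session_index, label`` followed by feature columns.
    Rows are kept sorted by ``(user_id, session_index)``; the pair must be
    unique and, within a user, strictly increasing (chronological order).
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in META_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        df = df.copy()
        df["session_index"] = df["session_index"].astype(int)
        df = df.sort_values(["user_id", "session_index"], kind="mergesort")
        df = df.reset_index(drop=True)
        dup = df.duplicated(subset=["user_id", "session_index"])
        if dup.any():
            rows = df.loc[dup, ["user_id", "session_index"]].to_records(index=False)
            raise ValueError(f"duplicate (user_id, session_index) pairs: {list(rows)}")
        ids = df["dataset_id"].unique()
        if len(ids) != 1:
            raise ValueError(f"a DatasetTable holds one dataset, got ids {list(ids)}")
        bad = set(df["label"].unique()) - {HIGH, LOW}
        if bad:
            raise ValueError(f"labels must be {HIGH!r}/{LOW!r}, got extras {bad}")
        self.df = df

    @property
    def dataset_id(self) -> str:
        return str(self.df["dataset_id"].iloc[0])

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.df.columns if c not in META_COLUMNS]

    @property
    def users(self) -> list[str]:
        return sorted(self.df["user_id"].unique())

    @property
    def n_sessions(self) -> int:
        return len(self.df)

    def features(self, columns: Sequence[str] | None = None) -> np.ndarray:
        cols = list(columns) if columns is not None else self.feature_names
        return self.df[cols].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return self.df["label"].to_numpy()

    def user_stream(self, user_id: str) -> pd.DataFrame:
        """All sessions of one user, chronologically ordered."""
        out = self.df[self.df["user_id"] == user_id]
        if out.empty:
            raise KeyError(f"unknown user {user_id!r}")
        return out

    @classmethod
    def from_examples(cls, examples: Sequence[LabelledExample]) -> "DatasetTable":
        if not examples:
            raise ValueError("cannot build a table from zero examples")
        names = examples[0].features.names
        rows = []
        for ex in examples:
            if ex.features.names != names:
                raise ValueError("all examples must share the feature schema")
            row = {
                "user_id": ex.user_id,
                "dataset_id": ex.dataset_id,
                "session_index": ex.session_index,
                "label": ex.label,
            }
            row.update(dict(zip(names, ex.features.values)))
            rows.append(row)
        return cls(pd.DataFrame(rows, columns=META_COLUMNS + list(names)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DatasetTable):
            return NotImplemented
        return self.df.equals(other.df)

    def __repr__(self) -> str:
        return (
            f"DatasetTable(dataset_id={self.dataset_id!r}, "
            f"n_sessions={self.n_sessions}, n_users={len(self.users)}, "
            f"n_features={len(self.feature_names)})"
        )
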