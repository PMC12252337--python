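"""Synthetic paired datasets with latent archetypes and controllable shift.

The feature-level generator emulates two cohorts ("A" and "B") of nightly
sleep-session feature vectors. Each session belongs to one of ``K`` latent
*session archetypes* (e.g. restful vs restless nights); features are
Gaussian around the archetype mean plus a per-user random offset. The binary
sleep-quality label follows a per-archetype logistic rule evaluated on the
*unshifted* features, so that dataset B's mean offset on a chosen fraction
of features is a pure covariate shift: P(Y | X) is identical across
datasets while the feature marginals differ.

Defaults mirror the study conditions the toolkit targets: two cohorts of 16
and 10 users observed for 30 nights each.

A raw-signal generator synthesizes one plausible sleep session (PPG with
cardiac and respiratory components, inter-beat intervals, skin temperature
drift, triaxial accelerometer bursts, and a consistent self-report) to
exercise the feature extractors; it is deliberately simple and is not
coupled to the feature-level generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    HIGH,
    LOW,
    META_COLUMNS,
    DatasetTable,
    IbiSeries,
    RawSignal,
    SelfReport,
    SleepSession,
)

__all__ = ["SyntheticConfig", "SyntheticPair", "generate_feature_pair",
           "generate_raw_session"]


@dataclass
class SyntheticConfig:
    """Conditions for the paired-dataset generator.

    ``archetype_separation`` is the pairwise Euclidean distance between
    archetype means, in units of the within-archetype noise SD.
    ``shift_delta`` is the per-feature mean offset added to dataset B on a
    random ``shift_fraction`` of the features.
    """

    n_users: tuple[int, int] = (16, 10)
    sessions_per_user: int = 30
    n_features: int = 12
    n_archetypes: int = 3
    archetype_separation: float = 5.0
    shift_delta: float = 0.0
    shift_fraction: float = 0.3
    user_effect_sd: float = 0.3
    label_noise: float = 0.1
    label_sharpness: float = 4.0
    label_rule: np.ndarray | None = None  # (K, n_features) logistic weights
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_archetypes < 1:
            raise ValueError("need at least one archetype")
        if not (0.0 <= self.shift_fraction <= 1.0):
            raise ValueError("shift_fraction must be in [0, 1]")
        if self.sessions_per_user < 1:
            raise ValueError("sessions_per_user must be >= 1")
        if not (0.0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must be in [0, 0.5)")
        if self.archetype_separation < 0 or self.user_effect_sd < 0:
            raise ValueError("separation and user_effect_sd must be >= 0")
        if min(self.n_users) < 1 or self.n_features < 1:
            raise ValueError("n_users and n_features must be positive")
        if self.label_rule is not None:
            w = np.asarray(self.label_rule, dtype=float)
            if w.shape != (self.n_archetypes, self.n_features):
                raise ValueError("label_rule must have shape (K, n_features)")


@dataclass
class SyntheticPair:
    """The generated pair of tables plus the planted ground truth."""

    table_a: DatasetTable
    table_b: DatasetTable
    shifted_features: list[str]
    archetype_means: np.ndarray
    label_rule: np.ndarray
    config: SyntheticConfig
    archetypes: pd.Series = field(repr=False, default=None)

    @property
    def tables(self) -> tuple[DatasetTable, DatasetTable]:
        return self.table_a, self.table_b


def _orthonormal_rows(rng: np.random.Generator, k: int, d: int) -> np.ndarray:
    """k mutually orthonormal d-vectors (random rotation); k <= d required."""
    if k > d:
        raise ValueError(f"need n_features >= n_archetypes ({k} > {d})")
    q, _ = np.linalg.qr(rng.standard_normal((d, k)))
    return q.T


def generate_feature_pair(config: SyntheticConfig) -> SyntheticPair:
    """Generate the paired datasets; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    d, k = config.n_features, config.n_archetypes
    # pairwise distance between means = archetype_separation
    means = _orthonormal_rows(rng, k, d) * (config.archetype_separation / np.sqrt(2.0))
    if config.label_rule is not None:
        rule = np.asarray(config.label_rule, dtype=float)
    else:
        rule = _orthonormal_rows(rng, k, d) * config.label_sharpness
    n_shift = int(round(config.shift_fraction * d))
    shifted_idx = np.sort(rng.choice(d, size=n_shift, replace=False))
    feature_names = [f"f{j:03d}" for j in range(d)]

    frames = []
    archetype_records = []
    for ds_id, n_u in zip(("A", "B"), config.n_users):
        rows = []
        for u in range(n_u):
            user_id = f"{ds_id}_u{u:02d}"
            offset = rng.normal(0.0, config.user_effect_sd, size=d)
            for s in range(config.sessions_per_user):
                arch = int(rng.integers(k))
                x0 = means[arch] + offset + rng.standard_normal(d)
                logit = rule[arch] @ (x0 - means[arch])
                p_high = 1.0 / (1.0 + np.exp(-logit))
                label = HIGH if rng.random() < p_high else LOW
                if rng.random() < config.label_noise:
                    label = LOW if label == HIGH else HIGH
                x = x0.copy()
                if ds_id == "B":
                    x[shifted_idx] += config.shift_delta
                row = {"user_id": user_id, "dataset_id": ds_id,
                       "session_index": s, "label": label}
                row.update(dict(zip(feature_names, x)))
                rows.append(row)
                archetype_records.append(arch)
        frames.append(pd.DataFrame(rows, columns=META_COLUMNS + feature_names))

    return SyntheticPair(
        table_a=DatasetTable(frames[0]),
        table_b=DatasetTable(frames[1]),
        shifted_features=[feature_names[j] for j in shifted_idx],
        archetype_means=means,
        label_rule=rule,
        config=config,
        archetypes=pd.Series(archetype_records, name="archetype"),
    )


def generate_raw_session(
    heart_rate_bpm: float = 60.0,
    breaths_per_min: float = 15.0,
    temp_c: float = 33.5,
    motion_level: float = 0.0,
    duration_s: float = 600.0,
    seed: int = 0,
    user_id: str = "synthetic",
    dataset_id: str = "synthetic",
    session_index: int = 0,
) -> SleepSession:
    """Synthesize one sleep session's raw signals and self-report.

    The PPG is a cardiac sinusoid amplitude-modulated at the respiratory
    rate; the IBI series has mean 60000 / heart_rate_bpm ms; skin
    temperature drifts slowly; the accelerometer holds gravity plus motion
    bursts scaled by ``motion_level``.
    """
    if not (30.0 <= heart_rate_bpm <= 200.0):
        raise ValueError(f"heart rate {heart_rate_bpm} outside 30-200 bpm")
    if not (4.0 <= breaths_per_min <= 30.0):
        raise ValueError(f"respiratory rate {breaths_per_min} outside 4-30 brpm")
    if duration_s <= 10.0:
        raise ValueError("duration must exceed 10 s")
    rng = np.random.default_rng(seed)
    f_card = heart_rate_bpm / 60.0
    f_resp = breaths_per_min / 60.0

    fs_ppg = 64.0
    t = np.arange(0.0, duration_s, 1.0 / fs_ppg)
    # cardiac pulse with respiratory amplitude modulation plus the
    # respiratory baseline wander the band-pass extractor relies on
    ppg = np.sin(2 * np.pi * f_card * t) * (1.0 + 0.3 * np.sin(2 * np.pi * f_resp * t))
    ppg += 0.4 * np.sin(2 * np.pi * f_resp * t)
    ppg += 0.05 * rng.standard_normal(t.size)
    bvp = RawSignal(ppg, sampling_rate=fs_ppg)

    fs_hr = 1.0
    n_hr = int(duration_s * fs_hr)
    hr = RawSignal(
        heart_rate_bpm + 1.5 * rng.standard_normal(n_hr), sampling_rate=fs_hr
    )

    fs_temp = 4.0
    tt = np.arange(0.0, duration_s, 1.0 / fs_temp)
    temp = temp_c + 0.3 * np.sin(2 * np.pi * tt / duration_s) + 0.01 * rng.standard_normal(tt.size)
    st = RawSignal(temp, sampling_rate=fs_temp)

    fs_acc = 32.0
    n_acc = int(duration_s * fs_acc)
    acc = np.zeros((n_acc, 3))
    acc[:, 2] = 1.0  # gravity, in g
    acc += 0.005 * rng.standard_normal((n_acc, 3))
    n_bursts = rng.poisson(motion_level * duration_s / 60.0)
    for _ in range(n_bursts):
        start = int(rng.integers(0, max(1, n_acc - int(2 * fs_acc))))
        length = int(rng.integers(int(0.5 * fs_acc), int(2 * fs_acc)))
        acc[start : start + length] += motion_level * rng.standard_normal(
            (min(length, n_acc - start), 3)
        )
    acc_sig = RawSignal(acc, sampling_rate=fs_acc, channel_names=["x", "y", "z"])

    mean_ibi_s = 60.0 / heart_rate_bpm
    n_beats = int(duration_s / mean_ibi_s) + 1
    intervals_s = np.clip(
        rng.normal(mean_ibi_s, 0.02 * mean_ibi_s, size=n_beats), 0.35, 1.9
    )
    offsets = np.cumsum(intervals_s)
    keep = offsets <= duration_s
    ibi = IbiSeries(offsets=offsets[keep], intervals=intervals_s[keep] * 1000.0)

    bedtime = 23 * 60.0
    wake = (bedtime + duration_s / 60.0) % (24 * 60)
    report = SelfReport(
        bedtime=bedtime,
        wake_time=wake,
        latency=10.0,
        awakenings=int(round(motion_level)),
        quality_score=8,
        scale_max=10,
    )
    return SleepSession(
        user_id=user_id,
        dataset_id=dataset_id,
        session_index=session_index,
        signals={"HR": hr, "TEMP": st, "ACC": acc_sig, "BVP": bvp, "IBI": ibi},
        report=report,
    )
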