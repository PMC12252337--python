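"""Per-modality feature extraction from sleep-session signals.

Each modality yields a fixed-dimension feature vector:

* ``HR``, ``ST``, ``ACC``, ``RP`` — 8 time-domain descriptive statistics plus
  4 FFT-based frequency-domain features (12 each). The accelerometer's three
  axes are collapsed to their Euclidean magnitude first; the respiration
  pattern (RP) is derived from the blood-volume pulse by band-passing the
  respiratory band.
* ``HRV`` — 12 time-domain and 7 frequency-domain heart-rate-variability
  statistics computed from the cleaned inter-beat-interval series (19).
* ``contextual`` — 4 objective self-report measures.

Concatenations: ``all-sensor-features`` = HR‖HRV‖ST‖ACC‖RP (67) and
``all-features`` = all-sensor-features‖contextual (71).

Sleep quality is binarized from the Likert score: on a 5-point scale, scores
of 4 or above are "high"; on a 10-point scale, scores of 7 or above.
"""

from __future__ import annotations

import numpy as np
from scipy import interpolate, signal as sps, stats

from .types import (
    HIGH,
    LOW,
    FeatureVector,
    IbiSeries,
    LabelledExample,
    RawSignal,
    SelfReport,
    SleepSession,
)

__all__ = [
    "TIME_FEATURE_NAMES",
    "FREQ_FEATURE_NAMES",
    "HRV_FEATURE_NAMES",
    "CONTEXTUAL_FEATURE_NAMES",
    "EmptyIbiError",
    "MissingSignalError",
    "extract_time_features",
    "extract_freq_features",
    "clean_ibi",
    "extract_hrv_features",
    "derive_respiration",
    "extract_contextual",
    "build_feature_vector",
    "binarize_quality",
    "session_to_example",
]

TIME_FEATURE_NAMES = ["mean", "std", "min", "max", "median", "skew", "kurtosis", "iqr"]
FREQ_FEATURE_NAMES = [
    "total_power",
    "dominant_freq",
    "spectral_entropy",
    "low_freq_fraction",
]
HRV_FEATURE_NAMES = [
    # time domain
    "mean_nn", "median_nn", "sdnn", "rmssd", "sdsd",
    "nn50", "pnn50", "nn20", "pnn20", "range_nn", "cvnn", "cvsd",
    # frequency domain
    "vlf_power", "lf_power", "hf_power", "total_power",
    "lf_hf_ratio", "lf_norm", "hf_norm",
]
CONTEXTUAL_FEATURE_NAMES = ["time_in_bed", "latency", "awakenings", "bedtime"]

#: HRV spectral bands (Hz), task-standard conventions.
HRV_BANDS = {"vlf": (0.0033, 0.04), "lf": (0.04, 0.15), "hf": (0.15, 0.4)}
#: Resampling rate (Hz) for the interpolated NN series before spectral estimation.
HRV_INTERP_RATE = 4.0


class EmptyIbiError(ValueError):
    """Every inter-beat interval was removed by cleaning: unusable session."""


class MissingSignalError(KeyError):
    """A modality's required signal is absent from the session."""


def _as_1d(signal: RawSignal | np.ndarray) -> np.ndarray:
    if isinstance(signal, RawSignal):
        return signal.magnitude()
    x = np.asarray(signal, dtype=float)
    if x.ndim == 2:
        return np.sqrt(np.sum(x**2, axis=1))
    return x


def extract_time_features(signal: RawSignal | np.ndarray) -> np.ndarray:
    """Eight time-domain descriptive statistics of a whole-night signal.

    Order: mean, sample std (ddof=1), min, max, median, skewness, excess
    kurtosis, interquartile range. Skewness and kurtosis are defined as 0 for
    zero-variance input.
    """
    x = _as_1d(signal)
    if x.size == 0:
        raise ValueError("cannot extract features from an empty signal")
    std = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    if std > 0:
        skew = float(stats.skew(x))
        kurt = float(stats.kurtosis(x))
    else:
        skew = kurt = 0.0
    q75, q25 = np.percentile(x, [75, 25])
    return np.array(
        [
            float(np.mean(x)),
            std,
            float(np.min(x)),
            float(np.max(x)),
            float(np.median(x)),
            skew,
            kurt,
            float(q75 - q25),
        ]
    )


def extract_freq_features(signal: RawSignal) -> np.ndarray:
    """Four FFT-based frequency-domain features.

    The signal is mean-removed and Hann-windowed before the FFT. Order: total
    spectral power, dominant frequency (Hz), spectral entropy normalized to
    [0, 1], and the fraction of power below half the Nyquist frequency.
    Zero-variance signals return all zeros by convention.
    """
    x = _as_1d(signal)
    fs = signal.sampling_rate if isinstance(signal, RawSignal) else 1.0
    n = x.size
    if n < 8:
        raise ValueError(f"need at least 8 samples for spectral features, got {n}")
    xc = (x - np.mean(x)) * np.hanning(n)
    spec = np.fft.rfft(xc)
    psd = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    psd, freqs = psd[1:], freqs[1:]  # drop the DC bin
    total = float(np.sum(psd))
    if total <= 0.0:
        return np.zeros(4)
    dominant = float(freqs[int(np.argmax(psd))])
    p = psd / total
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log(nz)) / np.log(len(p))) if len(p) > 1 else 0.0
    low = float(np.sum(psd[freqs < fs / 4.0]) / total)
    return np.array([total, dominant, entropy, low])


def clean_ibi(
    ibi: IbiSeries,
    lower_ms: float = 300.0,
    upper_ms: float = 2000.0,
    malik_threshold: float = 0.2,
) -> IbiSeries:
    """Physiological-range filtering followed by Malik's ectopic-beat rule.

    Step 1 drops intervals outside ``[lower_ms, upper_ms]``. Step 2 drops any
    interval differing by more than ``malik_threshold`` (20 %) from the last
    *accepted* interval; the first in-range interval seeds the comparison.
    Offsets of surviving beats are preserved.
    """
    if len(ibi) == 0:
        raise EmptyIbiError("empty inter-beat interval series")
    in_range = (ibi.intervals >= lower_ms) & (ibi.intervals <= upper_ms)
    offsets = ibi.offsets[in_range]
    intervals = ibi.intervals[in_range]

    keep = np.zeros(len(intervals), dtype=bool)
    last: float | None = None
    for i, iv in enumerate(intervals):
        if last is None or abs(iv - last) <= malik_threshold * last:
            keep[i] = True
            last = iv
    if not keep.any():
        raise EmptyIbiError("all intervals removed by cleaning")
    return IbiSeries(offsets=offsets[keep], intervals=intervals[keep])


def _band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> float:
    mask = (freqs >= band[0]) & (freqs < band[1])
    if not mask.any():
        return 0.0
    return float(np.trapezoid(psd[mask], freqs[mask]))


def extract_hrv_features(ibi: IbiSeries, min_intervals: int = 10) -> np.ndarray:
    """Nineteen heart-rate-variability statistics from a cleaned IBI series.

    Time domain (12): meanNN, medianNN, SDNN, RMSSD, SDSD, NN50, pNN50 (%),
    NN20, pNN20 (%), rangeNN, CVNN, CVSD. Frequency domain (7): VLF/LF/HF
    band powers, their total, LF/HF, and normalized LF and HF (% of LF+HF),
    estimated on the NN series interpolated to 4 Hz.
    """
    if len(ibi) < min_intervals:
        raise ValueError(
            f"need at least {min_intervals} intervals for HRV features, got {len(ibi)}"
        )
    nn = ibi.intervals
    diffs = np.diff(nn)
    mean_nn = float(np.mean(nn))
    sdnn = float(np.std(nn, ddof=1))
    rmssd = float(np.sqrt(np.mean(diffs**2)))
    sdsd = float(np.std(diffs, ddof=1)) if len(diffs) > 1 else 0.0
    nn50 = int(np.sum(np.abs(diffs) > 50.0))
    nn20 = int(np.sum(np.abs(diffs) > 20.0))
    time_feats = [
        mean_nn,
        float(np.median(nn)),
        sdnn,
        rmssd,
        sdsd,
        nn50,
        100.0 * nn50 / len(diffs),
        nn20,
        100.0 * nn20 / len(diffs),
        float(np.max(nn) - np.min(nn)),
        sdnn / mean_nn,
        rmssd / mean_nn,
    ]

    # Evenly resample the (irregular) NN series before Welch estimation.
    t = ibi.offsets
    grid = np.arange(t[0], t[-1], 1.0 / HRV_INTERP_RATE)
    if len(grid) < 8 or sdnn == 0.0:
        freq_feats = [0.0] * 7
    else:
        f = interpolate.interp1d(t, nn, kind="linear")
        series = f(grid) - np.mean(f(grid))
        nperseg = min(256, len(grid))
        freqs, psd = sps.welch(series, fs=HRV_INTERP_RATE, nperseg=nperseg)
        vlf = _band_power(freqs, psd, HRV_BANDS["vlf"])
        lf = _band_power(freqs, psd, HRV_BANDS["lf"])
        hf = _band_power(freqs, psd, HRV_BANDS["hf"])
        total = vlf + lf + hf
        lf_hf = lf / hf if hf > 0 else 0.0
        denom = lf + hf
        lf_norm = 100.0 * lf / denom if denom > 0 else 0.0
        hf_norm = 100.0 * hf / denom if denom > 0 else 0.0
        freq_feats = [vlf, lf, hf, total, lf_hf, lf_norm, hf_norm]
    return np.array(time_feats + freq_feats, dtype=float)


def derive_respiration(
    ppg: RawSignal,
    band: tuple[float, float] = (0.1, 0.5),
    output_rate: float = 4.0,
    order: int = 3,
) -> RawSignal:
    """Extract the respiration pattern from a PPG/BVP signal.

    Applies a zero-phase Butterworth band-pass over the respiratory band
    (0.1–0.5 Hz by default) and resamples to ``output_rate``. The result is a
    :class:`RawSignal` suitable for the standard time/frequency extractors.
    """
    if ppg.sampling_rate < 2.0:
        raise ValueError("PPG sampling rate must be at least 2 Hz")
    x = ppg.magnitude()
    sos = sps.butter(order, band, btype="bandpass", fs=ppg.sampling_rate, output="sos")
    # sosfiltfilt's default edge padding; shorter signals cannot be filtered.
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.size <= 3 * padlen:
        raise ValueError(
            f"signal too short for zero-phase filtering ({x.size} samples)"
        )
    filtered = sps.sosfiltfilt(sos, x)
    if output_rate != ppg.sampling_rate:
        from fractions import Fraction

        frac = Fraction(output_rate / ppg.sampling_rate).limit_denominator(1000)
        filtered = sps.resample_poly(filtered, frac.numerator, frac.denominator)
    return RawSignal(filtered, sampling_rate=output_rate, start_time=ppg.start_time)


def extract_contextual(report: SelfReport) -> np.ndarray:
    """Four objective self-report measures for the previous sleep session.

    Order: time in bed (minutes, wake − bed modulo 24 h), sleep latency
    (minutes), number of awakenings, bedtime (minutes since midnight).
    """
    tib = (report.wake_time - report.bedtime) % (24 * 60)
    return np.array(
        [tib, report.latency, float(report.awakenings), report.bedtime], dtype=float
    )


def _signal_features(sig: RawSignal) -> np.ndarray:
    return np.concatenate([extract_time_features(sig), extract_freq_features(sig)])


def _named(modality: str, names: list[str]) -> list[str]:
    return [f"{modality}.{n}" for n in names]


_SIGNAL_12 = TIME_FEATURE_NAMES + FREQ_FEATURE_NAMES


def _require(session: SleepSession, key: str, modality: str):
    sig = session.signals.get(key)
    if sig is None:
        raise MissingSignalError(
            f"modality {modality!r} requires signal {key!r}, absent from session "
            f"{session.user_id}/{session.session_index}"
        )
    return sig


def build_feature_vector(session: SleepSession, modality: str) -> FeatureVector:
    """Build the named feature vector of one modality from a session.

    Concatenation order for the multi-modality sets is fixed as
    HR‖HRV‖ST‖ACC‖RP (‖contextual for ``all-features``).
    """
    if modality == "HR":
        values = _signal_features(_require(session, "HR", modality))
        names = _named("HR", _SIGNAL_12)
    elif modality == "ST":
        values = _signal_features(_require(session, "TEMP", modality))
        names = _named("ST", _SIGNAL_12)
    elif modality == "ACC":
        sig = _require(session, "ACC", modality)
        mag = RawSignal(sig.magnitude(), sampling_rate=sig.sampling_rate,
                        start_time=sig.start_time)
        values = _signal_features(mag)
        names = _named("ACC", _SIGNAL_12)
    elif modality == "RP":
        rp = derive_respiration(_require(session, "BVP", modality))
        values = _signal_features(rp)
        names = _named("RP", _SIGNAL_12)
    elif modality == "HRV":
        ibi = clean_ibi(_require(session, "IBI", modality))
        values = extract_hrv_features(ibi)
        names = _named("HRV", HRV_FEATURE_NAMES)
    elif modality == "contextual":
        if session.report is None:
            raise MissingSignalError("modality 'contextual' requires a self-report")
        values = extract_contextual(session.report)
        names = _named("contextual", CONTEXTUAL_FEATURE_NAMES)
    elif modality in ("all-sensor-features", "all-features"):
        parts = [build_feature_vector(session, m) for m in ("HR", "HRV", "ST", "ACC", "RP")]
        if modality == "all-features":
            parts.append(build_feature_vector(session, "contextual"))
        values = np.concatenate([p.values for p in parts])
        names = [n for p in parts for n in p.names]
    else:
        raise ValueError(f"unknown modality {modality!r}")
    return FeatureVector(modality=modality, names=names, values=values)


def binarize_quality(score: int, scale_max: int) -> str:
    """Binarize a Likert sleep-quality score.

    5-point scale: high iff score >= 4. 10-point scale: high iff score >= 7.
    Other scales are rejected rather than silently generalized.
    """
    thresholds = {5: 4, 10: 7}
    if scale_max not in thresholds:
        raise ValueError(f"unsupported Likert scale maximum {scale_max}")
    if not (1 <= score <= scale_max):
        raise ValueError(f"score {score} outside [1, {scale_max}]")
    return HIGH if score >= thresholds[scale_max] else LOW


def session_to_example(session: SleepSession, modality: str) -> LabelledExample:
    """Extract features and the binary label from a complete session."""
    if session.report is None:
        raise ValueError("session has no self-report; cannot derive a label")
    fv = build_feature_vector(session, modality)
    label = binarize_quality(session.report.quality_score, session.report.scale_max)
    return LabelledExample(
        user_id=session.user_id,
        dataset_id=session.dataset_id,
        session_index=session.session_index,
        features=fv,
        label=label,
    )
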