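"""Feature-extraction correctness: frozen oracles, conventions, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sleepshift import (
    binarize_quality,
    build_feature_vector,
    clean_ibi,
    derive_respiration,
    extract_contextual,
    extract_freq_features,
    extract_hrv_features,
    extract_time_features,
)
from sleepshift.features import (
    EmptyIbiError,
    HRV_FEATURE_NAMES,
    MissingSignalError,
)
from sleepshift.types import IbiSeries, RawSignal, SelfReport


class TestTimeFeatures:
    def test_constant_signal_zero_variance_convention(self):
        out = extract_time_features(RawSignal([5.0, 5, 5, 5], 1.0))
        np.testing.assert_allclose(out, [5, 0, 5, 5, 5, 0, 0, 0])

    def test_small_vector_frozen_values(self):
        # oracle: mean 2.5, median 2.5, IQR 1.5 by linear-interp percentiles,
        # sample std with ddof=1 = sqrt(5/3)
        out = extract_time_features(RawSignal([1.0, 2, 3, 4], 1.0))
        expected = [2.5, np.sqrt(5.0 / 3.0), 1.0, 4.0, 2.5,
                    stats.skew([1, 2, 3, 4]), stats.kurtosis([1, 2, 3, 4]), 1.5]
        np.testing.assert_allclose(out, expected)

    def test_length_is_eight(self, rng):
        assert extract_time_features(RawSignal(rng.normal(size=50), 4.0)).shape == (8,)

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            extract_time_features(np.array([]))

    @given(shift=st.floats(-100, 100), seed=st.integers(0, 100))
    @settings(max_examples=25, deadline=None)
    def test_shift_equivariance(self, shift, seed):
        x = np.random.default_rng(seed).normal(size=40)
        base = extract_time_features(x)
        moved = extract_time_features(x + shift)
        assert moved[0] == pytest.approx(base[0] + shift, abs=1e-9)
        # std, skew, kurtosis, IQR are shift-invariant
        for i in (1, 5, 6, 7):
            assert moved[i] == pytest.approx(base[i], abs=1e-9)


class TestFreqFeatures:
    def test_sinusoid_dominant_frequency(self):
        t = np.arange(256) / 64.0
        sig = RawSignal(np.sin(2 * np.pi * 1.0 * t), 64.0)
        total, dom, entropy, low = extract_freq_features(sig)
        assert dom == pytest.approx(1.0, abs=64.0 / 256)  # within one bin
        assert total > 0

    def test_constant_signal_zero_power(self):
        out = extract_freq_features(RawSignal(np.full(64, 3.0), 8.0))
        np.testing.assert_allclose(out, 0.0)

    def test_white_noise_high_entropy(self, rng):
        sig = RawSignal(rng.normal(size=1024), 32.0)
        _, _, entropy, _ = extract_freq_features(sig)
        assert entropy > 0.9

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            extract_freq_features(RawSignal(np.ones(4), 1.0))


class TestCleanIbi:
    def _series(self, intervals_ms):
        offsets = np.cumsum(np.asarray(intervals_ms, float)) / 1000.0
        return IbiSeries(offsets=offsets, intervals=np.asarray(intervals_ms, float))

    def test_physiological_bounds(self):
        out = clean_ibi(self._series([250, 800, 900, 2500]))
        np.testing.assert_allclose(out.intervals, [800, 900])

    def test_malik_rule_compare_to_last_accepted(self):
        # 1300 is +44% vs 900 -> dropped; 920 is +2.2% vs 900 -> kept
        out = clean_ibi(self._series([800, 900, 1300, 920]))
        np.testing.assert_allclose(out.intervals, [800, 900, 920])

    def test_all_removed_is_error(self):
        with pytest.raises(EmptyIbiError):
            clean_ibi(self._series([250] * 5))

    @pytest.mark.parametrize("seed", range(5))
    def test_idempotence(self, seed):
        r = np.random.default_rng(seed)
        intervals = r.uniform(200, 2200, size=60)
        cleaned = clean_ibi(self._series(intervals))
        again = clean_ibi(cleaned)
        np.testing.assert_array_equal(again.intervals, cleaned.intervals)
        np.testing.assert_array_equal(again.offsets, cleaned.offsets)

    def test_offsets_preserved(self):
        series = self._series([800, 900, 1300, 920])
        out = clean_ibi(series)
        np.testing.assert_allclose(out.offsets, series.offsets[[0, 1, 3]])


class TestHrvFeatures:
    def _series(self, intervals_ms):
        offsets = np.cumsum(np.asarray(intervals_ms, float)) / 1000.0
        return IbiSeries(offsets=offsets, intervals=np.asarray(intervals_ms, float))

    def test_constant_series(self):
        out = extract_hrv_features(self._series([1000.0] * 100))
        named = dict(zip(HRV_FEATURE_NAMES, out))
        assert named["mean_nn"] == 1000.0
        assert named["sdnn"] == 0.0
        assert named["rmssd"] == 0.0
        assert named["pnn50"] == 0.0
        assert named["total_power"] == 0.0

    def test_alternating_series_hand_oracle(self):
        intervals = [900.0, 1100.0] * 20
        out = dict(zip(HRV_FEATURE_NAMES, extract_hrv_features(self._series(intervals))))
        # successive differences are all +/-200 ms
        assert out["rmssd"] == pytest.approx(200.0)
        assert out["pnn50"] == pytest.approx(100.0)
        assert out["pnn20"] == pytest.approx(100.0)
        assert out["mean_nn"] == pytest.approx(1000.0)
        assert out["range_nn"] == pytest.approx(200.0)
        assert out["cvnn"] == pytest.approx(out["sdnn"] / 1000.0)

    def test_length_is_nineteen(self, rng):
        intervals = rng.uniform(700, 1200, size=120)
        assert extract_hrv_features(self._series(intervals)).shape == (19,)

    def test_minimum_interval_guard(self):
        with pytest.raises(ValueError):
            extract_hrv_features(self._series([1000.0] * 5))


class TestRespiration:
    def test_respiratory_component_dominates(self):
        fs = 64.0
        t = np.arange(0, 120, 1 / fs)
        ppg = np.sin(2 * np.pi * 1.2 * t) + 0.5 * np.sin(2 * np.pi * 0.25 * t)
        rp = derive_respiration(RawSignal(ppg, fs))
        assert rp.sampling_rate == 4.0
        _, dom, _, _ = extract_freq_features(rp)
        assert dom == pytest.approx(0.25, abs=0.05)

    def test_drift_attenuated_at_least_20db(self):
        fs = 32.0
        t = np.arange(0, 300, 1 / fs)
        drift = np.sin(2 * np.pi * 0.05 * t)
        inband = np.sin(2 * np.pi * 0.25 * t)
        out_drift = derive_respiration(RawSignal(drift, fs)).samples
        out_band = derive_respiration(RawSignal(inband, fs)).samples
        # compare RMS in the central section (away from filter edges)
        sl = slice(len(out_drift) // 4, -len(out_drift) // 4)
        ratio = np.sqrt(np.mean(out_drift[sl] ** 2) / np.mean(out_band[sl] ** 2))
        assert 20 * np.log10(ratio) < -20.0

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            derive_respiration(RawSignal(np.ones(30), 16.0))


class TestContextualAndLabels:
    def test_cross_midnight_arithmetic(self):
        report = SelfReport(bedtime=23 * 60 + 30, wake_time=7 * 60 + 30,
                            latency=20, awakenings=1, quality_score=8, scale_max=10)
        np.testing.assert_allclose(extract_contextual(report), [480, 20, 1, 1410])

    def test_same_side_of_midnight(self):
        report = SelfReport(bedtime=60, wake_time=9 * 60, latency=0,
                            awakenings=0, quality_score=3, scale_max=5)
        assert extract_contextual(report)[0] == 480

    @pytest.mark.parametrize(
        "score,scale,expected",
        [(4, 5, "high"), (3, 5, "low"), (7, 10, "high"), (6, 10, "low"),
         (5, 5, "high"), (1, 10, "low")],
    )
    def test_binarize_thresholds(self, score, scale, expected):
        assert binarize_quality(score, scale) == expected

    def test_unsupported_scale_rejected(self):
        with pytest.raises(ValueError):
            binarize_quality(4, 7)


class TestFeatureVectors:
    @pytest.mark.parametrize(
        "modality,dim",
        [("HR", 12), ("HRV", 19), ("ST", 12), ("ACC", 12), ("RP", 12),
         ("contextual", 4), ("all-sensor-features", 67), ("all-features", 71)],
    )
    def test_dimensions(self, raw_session, modality, dim):
        fv = build_feature_vector(raw_session, modality)
        assert len(fv) == dim
        assert len(set(fv.names)) == dim

    def test_hr_without_ibi_succeeds(self, raw_session):
        session = type(raw_session)(
            user_id="u", dataset_id="d", session_index=0,
            signals={"HR": raw_session.signals["HR"]}, report=raw_session.report,
        )
        assert len(build_feature_vector(session, "HR")) == 12

    def test_missing_signal_names_modality(self, raw_session):
        session = type(raw_session)(
            user_id="u", dataset_id="d", session_index=0,
            signals={"HR": raw_session.signals["HR"]},
        )
        with pytest.raises(MissingSignalError, match="HRV"):
            build_feature_vector(session, "HRV")

    def test_extraction_is_deterministic(self, raw_session):
        a = build_feature_vector(raw_session, "all-features")
        b = build_feature_vector(raw_session, "all-features")
        np.testing.assert_array_equal(a.values, b.values)

    def test_concatenation_order(self, raw_session):
        fv = build_feature_vector(raw_session, "all-features")
        prefixes = [n.split(".")[0] for n in fv.names]
        boundaries = [prefixes.index(p) for p in ("HR", "HRV", "ST", "ACC", "RP",
                                                  "contextual")]
        assert boundaries == sorted(boundaries)
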