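"""Filtering, windowing, tensors and statistical features."""

import numpy as np
import pytest
from scipy import signal as sp_signal

from sepsislupi.exceptions import ConfigurationError, InputError
from sepsislupi.signal_features import (
    ECGSegment,
    QualityConfig,
    bandpass_filter,
    noise_fraction,
    privileged_ecg_features,
    regular_ecg_features,
    segment_windows,
    statistical_features,
)
from sepsislupi.taut_string import DEFAULT_EPSILONS, ts_feature_bank

RATE = 240.0


def _segment(samples, anchor="t0", rate=RATE):
    return ECGSegment(
        samples=samples, anchor=anchor, sampling_rate=rate,
        duration_s=len(samples) / rate,
    )


def _sinusoid(freq_hz, duration_s=20.0, rate=RATE):
    t = np.arange(int(duration_s * rate)) / rate
    return np.sin(2 * np.pi * freq_hz * t)


def _response_power(freq_hz, rate=RATE):
    """Oracle: squared magnitude of the forward-backward filter at freq."""
    sos = sp_signal.butter(2, (0.5, 40.0), btype="bandpass", fs=rate, output="sos")
    w, h = sp_signal.sosfreqz(sos, worN=[2 * np.pi * freq_hz / rate])
    return float(np.abs(h[0]) ** 4)  # filtfilt applies |H|^2 in amplitude


class TestBandpassFilter:
    # the 0.5 Hz high-pass edge transient decays over ~3 s; measure beyond it
    _STEADY = slice(int(3 * RATE), -int(3 * RATE))

    def test_60hz_mains_attenuated(self):
        seg = _segment(_sinusoid(60.0))
        out = bandpass_filter(seg).samples
        ratio = np.mean(out[self._STEADY] ** 2) / np.mean(seg.samples[self._STEADY] ** 2)
        assert ratio <= 0.25
        # and the measured attenuation agrees with the response oracle
        assert ratio == pytest.approx(_response_power(60.0), rel=0.1)

    def test_passband_10hz_preserved(self):
        seg = _segment(_sinusoid(10.0))
        out = bandpass_filter(seg).samples
        amp = np.max(np.abs(out[self._STEADY]))
        assert amp == pytest.approx(1.0, rel=0.10)

    def test_zero_in_zero_out_and_linearity(self, rng):
        zero = _segment(np.zeros(4800))
        assert np.allclose(bandpass_filter(zero).samples, 0.0)
        x = rng.normal(0, 1, 4800)
        f1 = bandpass_filter(_segment(3.0 * x)).samples
        f2 = 3.0 * bandpass_filter(_segment(x)).samples
        np.testing.assert_allclose(f1, f2, rtol=1e-9, atol=1e-12)

    def test_low_rate_rejected(self):
        seg = ECGSegment(np.zeros(300), anchor="t0", sampling_rate=60.0, duration_s=5.0)
        with pytest.raises(ConfigurationError):
            bandpass_filter(seg)


class TestSegmentWindows:
    def test_full_segment_splits_into_equal_halves(self):
        seg = ECGSegment(np.arange(144000, dtype=float), anchor="t0")
        w1, w2 = segment_windows(seg)
        assert w1.size == w2.size == 72000
        np.testing.assert_array_equal(np.concatenate([w1, w2]), seg.samples)

    def test_wrong_duration_rejected(self):
        seg = ECGSegment(np.zeros(599 * 240), anchor="t0", duration_s=599.0)
        with pytest.raises(InputError):
            segment_windows(seg)


class TestStatisticalFeatures:
    def test_constant_window(self):
        fs = statistical_features(np.full(100, 2.0))
        assert fs.mean == 2.0
        assert fs.variance == 0.0
        assert fs.shannon_entropy == 0.0
        assert fs.kurtosis == 0.0 and fs.skewness == 0.0

    def test_small_symmetric_window(self):
        fs = statistical_features([1.0, 2.0, 3.0, 4.0, 5.0])
        assert fs.mean == 3.0
        assert fs.median == 3.0
        assert fs.variance == pytest.approx(2.0)  # 1/n normalisation
        assert fs.skewness == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_kurtosis_near_three(self):
        x = np.random.default_rng(5).standard_normal(10_000)
        fs = statistical_features(x)
        assert fs.kurtosis == pytest.approx(3.0, abs=0.15)  # Pearson convention

    def test_mean_abs_fft_matches_direct_formula(self, rng):
        x = rng.normal(0, 1, 256)
        fs = statistical_features(x)
        assert fs.mean_abs_fft == pytest.approx(np.mean(np.abs(np.fft.fft(x))))

    def test_all_features_finite(self, rng):
        for _ in range(10):
            x = rng.normal(0, rng.uniform(1e-6, 100), int(rng.integers(2, 500)))
            assert np.all(np.isfinite(statistical_features(x).as_array()))


class TestFeatureTensors:
    def test_regular_tensor_is_2x5x6(self, rng):
        seg = _segment(rng.normal(0, 0.3, 4800), anchor="t0")
        feats = regular_ecg_features(seg)
        assert feats.tensor.shape == (2, 5, 6)
        assert feats.flatten().shape == (60,)

    def test_flattening_order_is_window_major(self, rng):
        seg = _segment(rng.normal(0, 0.3, 4800), anchor="t0")
        feats = regular_ecg_features(seg)
        flat = feats.flatten()
        # window 1, epsilon 2, feature 3 sits at 1*30 + 2*6 + 3
        assert flat[1 * 30 + 2 * 6 + 3] == feats.tensor[1, 2, 3]

    def test_tensor_matches_manual_composition(self, rng):
        samples = rng.normal(0, 0.3, 4800)
        seg = _segment(samples, anchor="t0")
        feats = regular_ecg_features(seg)
        half = samples.size // 2
        for w, window in enumerate((samples[:half], samples[half:])):
            manual = np.stack([fs.as_array() for fs in ts_feature_bank(window)])
            np.testing.assert_allclose(feats.tensor[w], manual)

    def test_privileged_counts_30_and_7(self, rng):
        seg = _segment(rng.normal(0, 0.3, 4800), anchor="t6")
        feats = privileged_ecg_features(seg)
        assert feats.ts_vector().shape == (30,)
        assert feats.sf_vector().shape == (7,)
        manual = np.stack([fs.as_array() for fs in ts_feature_bank(seg.samples)])
        np.testing.assert_allclose(feats.ts, manual)

    def test_anchor_mismatch_rejected(self, rng):
        seg_t6 = _segment(rng.normal(0, 0.3, 4800), anchor="t6")
        with pytest.raises(InputError):
            regular_ecg_features(seg_t6)
        seg_t0 = _segment(rng.normal(0, 0.3, 4800), anchor="t0")
        with pytest.raises(InputError):
            privileged_ecg_features(seg_t0)

    def test_determinism(self, rng):
        samples = rng.normal(0, 0.3, 4800)
        a = regular_ecg_features(_segment(samples, anchor="t0")).flatten()
        b = regular_ecg_features(_segment(samples.copy(), anchor="t0")).flatten()
        assert np.array_equal(a, b)


class TestNoiseFraction:
    def test_all_zero_segment_is_all_noise(self):
        seg = _segment(np.zeros(int(60 * RATE)))
        assert noise_fraction(seg) == 1.0

    def test_clean_pulse_train_is_clean(self):
        from sepsislupi.cohort import generate_ecg_segment

        rng = np.random.default_rng(2)
        seg = generate_ecg_segment(75, 0.03, 60.0, rng)
        assert noise_fraction(seg) == 0.0

    def test_half_zeroed_segment_scores_half(self):
        from sepsislupi.cohort import generate_ecg_segment

        rng = np.random.default_rng(2)
        seg = generate_ecg_segment(75, 0.03, 60.0, rng)
        samples = seg.samples.copy()
        samples[: samples.size // 2] = 0.0
        half = _segment(samples)
        assert noise_fraction(half) == pytest.approx(0.5, abs=1e-9)

    def test_out_of_range_amplitude_flagged(self):
        x = np.zeros(int(30 * RATE))
        x[: int(10 * RATE)] = 50.0 * np.sin(np.arange(int(10 * RATE)))
        seg = _segment(x)
        cfg = QualityConfig()
        assert noise_fraction(seg, cfg) == 1.0  # one saturated + two flat windows
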