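import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emgfusion.preprocess import (MASeries, bandpass_filter,
                                  detect_active_segments,
                                  moving_average_series, wavelet_denoise)


class TestWaveletDenoise:
    def test_all_zero_input_stays_zero(self):
        assert np.allclose(wavelet_denoise(np.zeros(256)), 0.0)

    def test_zero_threshold_is_perfect_reconstruction(self, rng):
        x = rng.normal(size=300)
        out = wavelet_denoise(x, rule="none")
        assert np.max(np.abs(out - x)) < 1e-8 * max(1.0, np.abs(x).max())

    def test_denoising_reduces_rms_error_vs_clean_tone(self, rng):
        # 80 Hz tone at 1 kHz with white noise at 0.3x amplitude
        t = np.arange(2048) / 1000.0
        clean = np.sin(2 * np.pi * 80 * t)
        noisy = clean + rng.normal(scale=0.3, size=clean.size)
        den = wavelet_denoise(noisy)
        err_out = np.sqrt(np.mean((den - clean) ** 2))
        err_in = np.sqrt(np.mean((noisy - clean) ** 2))
        assert err_out < err_in

    def test_output_length_never_grows(self, rng):
        for n in (16, 100, 257):
            assert wavelet_denoise(rng.normal(size=n)).size == n

    def test_too_short_input_raises(self):
        with pytest.raises(ValueError):
            wavelet_denoise(np.ones(8), levels=4)

    def test_unknown_wavelet_raises(self):
        with pytest.raises(ValueError):
            wavelet_denoise(np.ones(64), wavelet_name="nope")


class TestBandpass:
    def test_in_band_tone_passes_at_unit_gain(self):
        t = np.arange(4000) / 1000.0
        y = bandpass_filter(np.sin(2 * np.pi * 50 * t), fs=1000.0)
        amp = np.abs(y[1000:3000]).max()
        assert 0.95 <= amp <= 1.05

    def test_drift_surrogate_is_suppressed(self):
        t = np.arange(4000) / 1000.0
        y = bandpass_filter(np.sin(2 * np.pi * 1.0 * t), fs=1000.0)
        assert np.abs(y[1000:3000]).max() < 0.05

    def test_zero_in_zero_out(self):
        assert np.allclose(bandpass_filter(np.zeros(500), fs=1000.0), 0.0)

    def test_linearity(self, rng):
        x, y = rng.normal(size=(2, 1000))
        lhs = bandpass_filter(2.5 * x - 1.5 * y, fs=1000.0)
        rhs = 2.5 * bandpass_filter(x, 1000.0) - 1.5 * bandpass_filter(y, 1000.0)
        assert np.max(np.abs(lhs - rhs)) < 1e-8

    def test_band_outside_nyquist_raises(self):
        with pytest.raises(ValueError):
            bandpass_filter(np.zeros(100), fs=100.0, low=10, high=60)


class TestMovingAverage:
    def test_constant_input_gives_constant(self):
        mas = moving_average_series(np.full(20, 3.5), n=4)
        assert np.allclose(mas.values[3:], 3.5)
        assert np.all(np.isnan(mas.values[:3]))

    def test_small_example(self):
        mas = moving_average_series(np.array([1.0, 2, 3, 4]), n=2)
        assert np.allclose(mas.values[1:], [1.5, 2.5, 3.5])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_brute_force_window_mean(self, seed):
        r = np.random.default_rng(seed)
        x = r.normal(size=r.integers(7, 60))
        mas = moving_average_series(x, n=7)
        for t in range(6, x.size):
            assert mas.values[t] == pytest.approx(np.mean(x[t - 6: t + 1]))

    def test_window_longer_than_signal_raises(self):
        with pytest.raises(ValueError):
            moving_average_series(np.ones(5), n=6)


class TestSegmentDetection:
    @staticmethod
    def _mas(x, n=16):
        return moving_average_series(np.abs(x), n=n)

    def test_all_below_threshold_yields_empty(self):
        segs = detect_active_segments(self._mas(np.full(2000, 0.1)),
                                      threshold=1.0, min_duration=0.1, fs=1000)
        assert segs == []

    def test_step_plateau_recovered_within_window(self):
        fs, n = 1000, 16
        x = np.concatenate([np.zeros(fs), np.full(2 * fs, 5.0), np.zeros(fs)])
        segs = detect_active_segments(self._mas(x, n), threshold=1.0,
                                      min_duration=0.5, fs=fs)
        assert len(segs) == 1
        assert abs(segs[0].start - fs) <= n
        assert abs(segs[0].end - 3 * fs) <= n
        assert segs[0].peak_mas == pytest.approx(5.0)

    def test_zero_threshold_on_positive_signal_spans_defined_region(self):
        x = np.abs(np.random.default_rng(0).normal(size=1000)) + 0.1
        mas = self._mas(x, 16)
        segs = detect_active_segments(mas, threshold=0.0, min_duration=0.1,
                                      fs=1000)
        assert len(segs) == 1
        assert segs[0].start == 15 and segs[0].end == 1000

    def test_invariant_to_joint_positive_rescaling(self, rng):
        x = rng.normal(size=3000) * (1 + np.sin(np.arange(3000) / 300))
        mas = self._mas(x)
        a = detect_active_segments(mas, 0.8, 0.05, 1000)
        mas2 = MASeries(mas.values * 7.3, mas.window, mas.source)
        b = detect_active_segments(mas2, 0.8 * 7.3, 0.05, 1000)
        assert [(s.start, s.end) for s in a] == [(s.start, s.end) for s in b]

    def test_segments_sorted_and_disjoint(self, rng):
        x = (rng.normal(size=6000) *
             (np.sin(np.arange(6000) / 150) > 0).astype(float))
        segs = detect_active_segments(self._mas(x), 0.1, 0.05, 1000,
                                      merge_gap=0.05)
        for a, b in zip(segs, segs[1:]):
            assert a.end <= b.start
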