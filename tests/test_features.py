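import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emgfusion.features import (VMDConfig, band_power,
                                build_feature_sequence, fd_features,
                                td_features, vmd, welch_psd)
from emgfusion.io_core import Recording
from emgfusion.preprocess import ActiveSegment


class TestTimeDomain:
    def test_constant_signal(self):
        mav, rms, wl, zc = td_features(np.full(10, -3.0))
        assert (mav, rms, wl, zc) == (3.0, 3.0, 0.0, 0)

    def test_small_example(self):
        mav, rms, wl, zc = td_features(np.array([1.0, -2, 3]), zc_deadband=0)
        assert mav == pytest.approx(2.0)
        assert rms == pytest.approx(np.sqrt(14 / 3))
        assert wl == pytest.approx(8.0)
        assert zc == 2

    def test_alternating_signs_count_all_crossings(self):
        x = np.array([1.0, -1] * 8)
        assert td_features(x)[3] == x.size - 1

    @given(st.floats(-50, 50).filter(lambda a: abs(a) > 1e-3),
           st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, a, seed):
        x = np.random.default_rng(seed).normal(size=30)
        mav, rms, wl, zc = td_features(x)
        mav2, rms2, wl2, zc2 = td_features(a * x)
        assert mav2 == pytest.approx(abs(a) * mav, rel=1e-9)
        assert rms2 == pytest.approx(abs(a) * rms, rel=1e-9)
        assert wl2 == pytest.approx(abs(a) * wl, rel=1e-9)
        assert zc2 == zc


class TestVMD:
    def test_single_tone_center_frequency(self):
        t = np.arange(2000) / 1000.0
        res = vmd(np.sin(2 * np.pi * 40 * t), K=1, fs=1000.0)
        assert abs(res.center_freqs[0] - 40.0) < 1.0

    def test_two_tone_separation(self):
        t = np.arange(2000) / 1000.0
        x = np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 80 * t)
        res = vmd(x, K=2, fs=1000.0)
        assert np.all(np.diff(res.center_freqs) > 0)
        assert abs(res.center_freqs[0] - 10.0) < 2.0
        assert abs(res.center_freqs[1] - 80.0) < 2.0

    def test_mode_sum_reconstructs_smooth_tones(self):
        t = np.arange(2000) / 1000.0
        x = np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 80 * t)
        res = vmd(x, K=2, fs=1000.0)
        resid = np.linalg.norm(res.modes.sum(0) - x) / np.linalg.norm(x)
        assert resid < 0.05

    def test_modes_are_narrow_band_around_center(self, rng):
        x = rng.normal(size=1500)
        res = vmd(x, K=3, fs=1000.0)
        for mode, cf in zip(res.modes, res.center_freqs):
            f, p = welch_psd(mode, 1000.0, nperseg=512)
            centroid = float(f @ p / p.sum())
            assert abs(centroid - cf) < 25.0

    def test_too_short_input_raises(self):
        with pytest.raises(ValueError):
            vmd(np.ones(5), K=4)

    def test_nonconvergence_flagged_not_raised(self, rng):
        res = vmd(rng.normal(size=600), K=4, max_iter=2)
        assert res.converged is False and res.n_iter == 2


class TestWelch:
    def test_zero_signal_zero_psd(self):
        _, p = welch_psd(np.zeros(1000), 1000.0, nperseg=256)
        assert np.allclose(p, 0.0)

    def test_tone_peak_at_its_frequency(self):
        t = np.arange(4000) / 1000.0
        f, p = welch_psd(np.sin(2 * np.pi * 50 * t), 1000.0, nperseg=1000)
        assert f[np.argmax(p)] == pytest.approx(50.0, abs=f[1] - f[0])

    def test_white_noise_total_power_matches_variance(self):
        x = np.random.default_rng(99).normal(scale=2.0, size=2**17)
        f, p = welch_psd(x, 1000.0, nperseg=1024)
        total = np.sum(p) * (f[1] - f[0])
        assert total == pytest.approx(4.0, rel=0.1)

    def test_linearity_in_expectation_for_independent_noise(self):
        r1 = np.random.default_rng(1).normal(size=2**16)
        r2 = np.random.default_rng(2).normal(scale=1.5, size=2**16)
        f, p12 = welch_psd(r1 + r2, 1000.0, nperseg=1024)
        _, p1 = welch_psd(r1, 1000.0, nperseg=1024)
        _, p2 = welch_psd(r2, 1000.0, nperseg=1024)
        assert band_power(f, p12) == pytest.approx(
            band_power(f, p1) + band_power(f, p2), rel=0.1)

    def test_nperseg_longer_than_signal_raises(self):
        with pytest.raises(ValueError):
            welch_psd(np.zeros(100), 1000.0, nperseg=256)


class TestSpectralFeatures:
    def test_single_line(self):
        f = np.array([10.0, 50.0, 90.0])
        p = np.array([0.0, 3.0, 0.0])
        mdf, mpf = fd_features(f, p)
        assert mdf == pytest.approx(50.0) and mpf == pytest.approx(50.0)

    def test_flat_spectrum_is_symmetric(self):
        f = np.linspace(0, 100, 101)
        mdf, mpf = fd_features(f, np.ones(101))
        assert mdf == pytest.approx(50.0, abs=0.5)
        assert mpf == pytest.approx(50.0)

    def test_two_equal_lines_median_at_midpoint(self):
        f = np.array([20.0, 80.0])
        mdf, mpf = fd_features(f, np.array([1.0, 1.0]))
        assert mdf == pytest.approx(50.0) and mpf == pytest.approx(50.0)

    def test_invariant_to_uniform_psd_rescaling(self, rng):
        f = np.linspace(0, 200, 64)
        p = rng.uniform(0.1, 2.0, 64)
        assert fd_features(f, p) == pytest.approx(fd_features(f, 17.0 * p))

    def test_zero_psd_raises(self):
        with pytest.raises(ValueError):
            fd_features(np.arange(4.0), np.zeros(4))


class TestFeatureSequence:
    @staticmethod
    def _rec(rng, n=1500, fs=500.0):
        return Recording(rng.normal(size=(6, n)), fs=fs)

    def test_segment_equal_to_window_gives_one_vector(self, rng):
        rec = self._rec(rng)
        seq = build_feature_sequence(rec, ActiveSegment(0, 250),
                                     window_len=0.5, stride=0.25)
        assert len(seq) == 1

    def test_half_stride_window_count(self, rng):
        rec = self._rec(rng)
        seq = build_feature_sequence(rec, ActiveSegment(0, 500),
                                     window_len=0.5, stride=0.25)
        assert len(seq) == 3

    def test_vector_layout_length(self, rng):
        rec = self._rec(rng)
        K = 3
        seq = build_feature_sequence(rec, ActiveSegment(0, 250), 0.5, 0.25,
                                     vmd_cfg=VMDConfig(K=K))
        assert seq.vectors.shape[1] == 6 * (4 + 2 + K)
        assert len(seq.feature_names) == seq.vectors.shape[1]

    def test_segment_shorter_than_window_raises(self, rng):
        rec = self._rec(rng)
        with pytest.raises(ValueError):
            build_feature_sequence(rec, ActiveSegment(0, 100), 0.5, 0.25)
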