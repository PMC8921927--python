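"""Windowing and the MAV / spectral-centroid / wavelet-energy features."""

import logging

import numpy as np
import pytest
import pywt
from hypothesis import given, settings
from hypothesis import strategies as st

import emgangle as eg

FS = 1000.0


def brute_force_dft(x):
    """O(N^2) direct evaluation of X(k) = sum_n x(n) W_N^{nk}."""
    x = np.asarray(x, dtype=complex)
    n = x.size
    k = np.arange(n)
    W = np.exp(-2j * np.pi * np.outer(k, k) / n)
    return W @ x


def _rec(samples, rate=FS, channels=None):
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] == 1:
        samples = samples.T
    channels = channels or tuple(f"ch{i}" for i in range(samples.shape[1]))
    return eg.EmgRecording(rate, channels, samples)


class TestWindowing:
    def test_default_trial_yields_39_overlapping_windows(self):
        rec = _rec(np.zeros(5000))
        windows, centers = eg.window_signal(rec, eg.WindowingSpec())
        assert windows.shape == (39, 250, 1)
        assert centers[0] == pytest.approx((0 + 249) / 2 / FS)

    def test_non_overlapping_tiling(self):
        rec = _rec(np.zeros(5000))
        windows, _ = eg.window_signal(rec, eg.WindowingSpec(stride_ms=250.0))
        assert windows.shape[0] == 20

    def test_too_short_recording_raises(self):
        with pytest.raises(ValueError, match="shorter"):
            eg.window_signal(_rec(np.zeros(100)), eg.WindowingSpec())

    def test_steady_state_samples_covered_window_over_stride_times(self):
        rec = _rec(np.zeros(2000))
        spec = eg.WindowingSpec()
        win = spec.window_samples(FS)
        stride = spec.stride_samples(FS)
        counts = np.zeros(2000)
        n_windows = eg.window_signal(rec, spec)[0].shape[0]
        for s in range(n_windows):
            counts[s * stride : s * stride + win] += 1
        steady = counts[win : (n_windows - 1) * stride]
        assert np.all(steady == int(np.ceil(win / stride)))


class TestMav:
    def test_hand_oracle_and_degenerate_cases(self):
        assert eg.mav([1, -2, 3, -4]) == pytest.approx(2.5)
        assert eg.mav(np.zeros(10)) == 0.0
        assert eg.mav(np.full(7, -3.0)) == 3.0
        with pytest.raises(ValueError):
            eg.mav([])

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-100, max_value=100), min_size=1, max_size=32
        ),
        st.floats(min_value=-10, max_value=10),
    )
    def test_scale_equivariance(self, x, a):
        assert eg.mav(np.multiply(a, x)) == pytest.approx(abs(a) * eg.mav(x))


class TestDft:
    def test_matches_brute_force_direct_sum(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(2, 65)
            x = rng.standard_normal(n)
            expected = brute_force_dft(x)
            got = eg.dft(x)
            assert np.max(np.abs(got - expected)) <= 1e-9 * np.max(np.abs(expected))

    def test_impulse_and_round_trip(self):
        assert np.allclose(eg.dft([1, 0, 0, 0]), np.ones(4))
        rng = np.random.default_rng(1)
        x = rng.standard_normal(50)
        assert np.max(np.abs(eg.idft(eg.dft(x)) - x)) <= 1e-9

    def test_parseval(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(64)
        X = eg.dft(x)
        assert np.sum(np.abs(x) ** 2) == pytest.approx(
            np.sum(np.abs(X) ** 2) / x.size
        )


class TestDftFeature:
    def test_pure_tone_centroid_within_one_bin(self):
        t = np.arange(250) / FS
        value = eg.dft_feature(np.sin(2 * np.pi * 100 * t), FS)
        assert value == pytest.approx(100.0, abs=4.0)

    def test_white_noise_centroid_approaches_band_midpoint(self):
        rng = np.random.default_rng(3)
        values = [
            eg.dft_feature(rng.standard_normal(250), FS) for _ in range(300)
        ]
        assert np.mean(values) == pytest.approx(110.0, abs=6.0)

    def test_zero_window_returns_midpoint_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="emgangle.features"):
            value = eg.dft_feature(np.zeros(250), FS)
        assert value == 110.0
        assert any("no power" in r.message for r in caplog.records)


class TestWtFeature:
    def test_zero_window_and_monotonicity(self):
        assert eg.wt_feature(np.zeros(250)) == 0.0
        rng = np.random.default_rng(4)
        x = rng.standard_normal(250)
        assert eg.wt_feature(2.0 * x) > eg.wt_feature(x)

    def test_detail_energy_matches_band_reconstruction(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(256)
        spec = eg.WaveletSpec()
        coeffs = pywt.wavedec(x, spec.wavelet, level=spec.level, mode="periodization")
        detail_energy = np.sum(coeffs[1] ** 2)
        only_band = [np.zeros_like(c) for c in coeffs]
        only_band[1] = coeffs[1]
        recon = pywt.waverec(only_band, spec.wavelet, mode="periodization")
        assert detail_energy == pytest.approx(np.sum(recon**2), rel=1e-6)
        assert eg.wt_feature(x, spec) == pytest.approx(np.log1p(detail_energy))

    def test_window_too_short_for_level(self):
        with pytest.raises(ValueError, match="level"):
            eg.wt_feature(np.zeros(8), eg.WaveletSpec(level=6))


class TestExtractFeatures:
    def test_five_channels_give_fifteen_channel_major_columns(self, clean_trial):
        _, rec, _ = clean_trial
        fm = eg.extract_features(rec)
        assert fm.n_features == 15
        assert fm.feature_names[:4] == (
            "pronator_teres_mav",
            "pronator_teres_dft",
            "pronator_teres_wt",
            "flexor_carpi_radialis_mav",
        )

    def test_single_channel_gives_three_columns(self):
        rng = np.random.default_rng(6)
        fm = eg.extract_features(_rec(rng.standard_normal(1000)))
        assert fm.n_features == 3

    def test_feature_count_scales_with_channels(self):
        rng = np.random.default_rng(7)
        for n_ch in (2, 4):
            rec = _rec(rng.standard_normal((1000, n_ch)))
            assert eg.extract_features(rec).n_features == 3 * n_ch
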