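"""Wavelet band decomposition, band features, and dysfunction statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hrvbench as hb
from hrvbench.wavelet import (band_frequency_grid, detect_dysfunctions,
                              dysfunction_features, WaveletBandSeries)

from conftest import tachogram_from_values


def tone_tachogram(freq, amp=30.0, fs=10.0, duration=300.0):
    t = np.arange(int(duration * fs)) / fs
    return tachogram_from_values(800.0 + amp * np.sin(2 * np.pi * freq * t), fs)


class TestCwtBandSeries:
    def test_scale_frequency_arithmetic(self):
        # a = f_c * f_s / f with f_c = 0.5 and f_s = 10 Hz at f = 0.1 Hz
        assert 0.5 * 10.0 / 0.1 == pytest.approx(50.0)
        # the implementation's grids obey the same mapping
        import pywt
        fc = pywt.central_frequency("coif5")
        wbs = hb.cwt_band_series(tone_tachogram(0.25))
        freqs = band_frequency_grid("LF")
        np.testing.assert_allclose(wbs.scales["LF"], fc * 10.0 / freqs)

    def test_voices_per_octave(self):
        for band, (lo, hi) in (("VLF", (0.003, 0.04)), ("LF", (0.04, 0.15)),
                               ("HF", (0.15, 0.4))):
            grid = band_frequency_grid(band)
            octaves = math.log2(hi / lo)
            assert (grid.size - 1) / octaves >= 8

    def test_hf_tone_dominates_wavelet_bands(self):
        feats = hb.wavelet_features(tone_tachogram(0.25))
        assert feats["HFn(wt)"] > 0.8

    def test_localization_of_switched_tone(self):
        """LF power concentrates in the half where the 0.1 Hz tone is on."""
        t = np.arange(3000) / 10.0
        x = 800.0 + np.where(t > 150.0, 30 * np.sin(2 * np.pi * 0.1 * t), 0.0)
        wbs = hb.cwt_band_series(tachogram_from_values(x))
        first = wbs.lf_t[wbs.t_s < 140.0].mean()
        second = wbs.lf_t[wbs.t_s > 160.0].mean()
        assert second > 5 * first

    def test_stationary_tone_band_series_is_stable(self):
        wbs = hb.cwt_band_series(tone_tachogram(0.25))
        inner = slice(300, 2700)  # clip cone-of-influence edges
        assert wbs.hf_t[inner].std() < 0.5 * wbs.hf_t[inner].mean()


class TestWaveletBandFeatures:
    def test_quadratic_energy_scaling(self):
        a = hb.wavelet_features(tone_tachogram(0.25, amp=15.0))
        b = hb.wavelet_features(tone_tachogram(0.25, amp=30.0))
        assert b["HF(wt)"] == pytest.approx(4 * a["HF(wt)"], rel=0.02)
        for key in ("HFn(wt)", "LFn(wt)", "VLFn(wt)"):
            assert b[key] == pytest.approx(a[key], abs=0.02)

    def test_normalized_triple_sums_to_one(self):
        x = 800 + 20 * np.random.default_rng(0).standard_normal(3000)
        f = hb.wavelet_features(tachogram_from_values(x))
        assert f["HFn(wt)"] + f["LFn(wt)"] + f["VLFn(wt)"] == pytest.approx(1.0)

    def test_energy_consistency_with_fourier(self):
        """Wavelet TP rank-correlates with Fourier TP across 30 subjects."""
        from scipy.stats import spearmanr
        rng = np.random.default_rng(5)
        tp_fr, tp_wt = [], []
        for _ in range(30):
            amp = rng.uniform(5, 50)
            x = 800 + amp * rng.standard_normal(1200)
            tach = tachogram_from_values(x)
            tp_fr.append(hb.spectral_features(tach)["TP(Fr)"])
            tp_wt.append(hb.wavelet_features(tach)["TP(wt)"])
        rho = spearmanr(tp_fr, tp_wt).statistic
        assert rho > 0.8


class TestDysfunctions:
    def test_hand_example(self):
        """Two runs above Δ=10 with area (2+5)·0.1 + 1·0.1."""
        ratio = np.array([2.0, 12.0, 15.0, 3.0, 11.0, 2.0])
        d = detect_dysfunctions(ratio, dt_s=0.1, delta=10.0)
        assert d.nd == 2
        assert d.ratio_max == pytest.approx(15.0)
        assert d.intensity == pytest.approx(0.8)

    def test_all_below_threshold(self):
        d = detect_dysfunctions(np.full(100, 3.0), 0.1, 10.0)
        assert d.nd == 0 and d.intensity == 0.0 and math.isnan(d.ratio_max)

    def test_matches_brute_force_scanner(self):
        """Vectorized detector equals a per-sample run scanner (20 seeds)."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ratio = rng.exponential(6.0, 400)
            ratio[rng.random(400) < 0.05] = np.nan
            d = detect_dysfunctions(ratio, 0.1, 10.0)
            # brute force
            nd, intensity, rmax, in_run = 0, 0.0, -np.inf, False
            for v in ratio:
                above = np.isfinite(v) and v > 10.0
                if above:
                    if not in_run:
                        nd += 1
                    intensity += (v - 10.0) * 0.1
                    rmax = max(rmax, v)
                in_run = above
            assert d.nd == nd
            assert d.intensity == pytest.approx(intensity)
            if nd:
                assert d.ratio_max == pytest.approx(rmax)

    @given(delta=st.floats(1.0, 30.0), seed=st.integers(0, 50))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_delta(self, delta, seed):
        """Raising Δ never increases the excursion count or area."""
        ratio = np.random.default_rng(seed).exponential(8.0, 300)
        lo = detect_dysfunctions(ratio, 0.1, delta)
        hi = detect_dysfunctions(ratio, 0.1, delta + 5.0)
        assert hi.intensity <= lo.intensity + 1e-12
        assert hi.nd <= lo.nd or hi.intensity <= lo.intensity

    def test_intensity_zero_iff_no_dysfunction(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            ratio = rng.exponential(5.0, 200)
            d = detect_dysfunctions(ratio, 0.1, 10.0)
            assert (d.intensity == 0.0) == (d.nd == 0)

    def test_mean_intensity_mode(self):
        ratio = np.array([2.0, 12.0, 15.0, 3.0, 11.0, 2.0])
        d = detect_dysfunctions(ratio, 0.1, 10.0, intensity_mode="mean")
        assert d.intensity == pytest.approx((12 + 15 + 11) / 3)

    def test_smoothing_suppresses_single_sample_spike(self):
        ratio = np.full(600, 2.0)
        ratio[300] = 50.0
        wbs = WaveletBandSeries(
            t_s=np.arange(600) / 10.0, hf_t=np.ones(600), lf_t=ratio.copy(),
            vlf_t=np.ones(600), ratio_t=ratio, fs_hz=10.0)
        smoothed = dysfunction_features(wbs, delta=10.0, smooth_window_s=1.0)
        raw = dysfunction_features(wbs, delta=10.0, smooth_window_s=0.0)
        assert raw.nd == 1 and smoothed.nd == 0
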