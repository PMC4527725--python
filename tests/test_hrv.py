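"""HRV metrics: definitional oracles, spectral recovery, and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import shockhrv as sh
from shockhrv.hrv import PIG_BANDS, Spectrum, UniformTachogram, WelchConfig


def brute_force_time_domain(nn):
    """Independent definitional computation of variance/SDNN/RMSSD."""
    nn = np.asarray(nn, dtype=float)
    mean = sum(nn) / len(nn)
    var = sum((v - mean) ** 2 for v in nn) / (len(nn) - 1)
    diffs = [nn[i + 1] - nn[i] for i in range(len(nn) - 1)]
    rmssd = (sum(d**2 for d in diffs) / len(diffs)) ** 0.5
    return var, var**0.5, rmssd


def brute_force_periodogram(x, fs):
    """One-sided DFT periodogram density, computed from the definition."""
    n = len(x)
    freqs = np.arange(n // 2 + 1) * fs / n
    psd = np.empty(len(freqs))
    for k in range(len(freqs)):
        xk = sum(x[j] * np.exp(-2j * np.pi * k * j / n) for j in range(n))
        p = abs(xk) ** 2 / (fs * n)
        if 0 < k < n / 2:
            p *= 2.0
        psd[k] = p
    return freqs, psd


class TestTimeDomain:
    def test_worked_example(self):
        td = sh.time_domain(sh.RRISeries.from_nn([800, 810, 790, 805]))
        assert td.variance == pytest.approx(72.9167, abs=1e-4)
        assert td.sdnn == pytest.approx(8.5391, abs=1e-4)
        assert td.rmssd == pytest.approx(15.5456, abs=1e-4)

    def test_constant_series_has_zero_variability(self, constant_rri):
        td = sh.time_domain(constant_rri)
        assert td.variance == td.sdnn == td.rmssd == 0.0

    def test_translation_invariance(self):
        nn = np.array([820.0, 790.0, 760.0, 805.0, 840.0])
        a = sh.time_domain(sh.RRISeries.from_nn(nn))
        b = sh.time_domain(sh.RRISeries.from_nn(nn + 50.0))
        assert b.variance == pytest.approx(a.variance, rel=1e-12)
        assert b.rmssd == pytest.approx(a.rmssd, rel=1e-12)

    @given(st.lists(st.floats(min_value=400, max_value=1500), min_size=2, max_size=400))
    @settings(derandomize=True, max_examples=60)
    def test_matches_brute_force_definitions(self, nn):
        td = sh.time_domain(sh.RRISeries.from_nn(nn))
        var, sdnn, rmssd = brute_force_time_domain(nn)
        assert td.variance == pytest.approx(var, rel=1e-9, abs=1e-12)
        assert td.sdnn == pytest.approx(sdnn, rel=1e-9, abs=1e-12)
        assert td.rmssd == pytest.approx(rmssd, rel=1e-9, abs=1e-12)

    def test_refuses_ectopic_and_short_series(self, constant_rri):
        dirty = sh.inject_ectopy(constant_rri, 0.1, 0.5, seed=0)
        with pytest.raises(ValueError):
            sh.time_domain(dirty)
        with pytest.raises(ValueError):
            sh.time_domain(sh.RRISeries.from_nn([800.0]))


class TestResampling:
    def test_constant_series_resamples_to_zero_after_detrend(self, constant_rri):
        tach = sh.resample_tachogram(constant_rri)
        assert np.allclose(tach.values, 0.0, atol=1e-9)

    def test_lf_sinusoid_reproduced_within_one_percent(self):
        rri = sh.generate_rri_series(
            sh.RRIGenParams(mean_rr=800, lf_amp=20, duration=300, seed=1)
        )
        tach = sh.resample_tachogram(rri)
        # amplitude of the resampled oscillation matches the generator
        assert np.sqrt(2 * np.var(tach.values)) == pytest.approx(20.0, rel=0.01)

    def test_aliasing_guard(self, constant_rri):
        with pytest.raises(ValueError):
            sh.resample_tachogram(constant_rri, rate=3.0)


class TestPSD:
    def test_zero_series_has_zero_psd(self):
        tach = UniformTachogram(10.0, np.zeros(3000))
        spec = sh.estimate_psd(tach)
        assert np.all(spec.psd == 0.0)

    def test_peak_located_at_oscillation_frequency(self):
        rri = sh.generate_rri_series(
            sh.RRIGenParams(mean_rr=800, lf_amp=20, duration=300, seed=0)
        )
        spec = sh.estimate_psd(sh.resample_tachogram(rri))
        peak = spec.frequencies[np.argmax(spec.psd)]
        bin_width = spec.frequencies[1] - spec.frequencies[0]
        assert abs(peak - 0.05) <= bin_width

    @pytest.mark.parametrize("n", [64, 200, 256])
    def test_single_boxcar_segment_equals_brute_force_dft(self, n):
        rng = np.random.default_rng(n)
        x = rng.normal(0, 10, n)
        rate = 10.0
        tach = UniformTachogram(rate, x)
        spec = sh.estimate_psd(
            tach, WelchConfig(segment_s=n / rate, overlap=0.0, window="boxcar",
                              detrend=False)
        )
        freqs, psd = brute_force_periodogram(x, rate)
        assert np.allclose(spec.frequencies, freqs, rtol=0, atol=1e-12)
        assert np.allclose(spec.psd, psd, rtol=1e-6, atol=1e-9)

    def test_segment_longer_than_series_is_rejected_with_guidance(self):
        tach = UniformTachogram(10.0, np.zeros(100))
        with pytest.raises(ValueError, match="shorten"):
            sh.estimate_psd(tach)


class TestBandPowers:
    def test_two_line_spectrum_direct_arithmetic(self):
        # all power concentrated near 0.05 Hz (100 ms²) and 0.5 Hz (50 ms²)
        f = np.arange(0.0, 2.001, 0.001)
        psd = np.zeros_like(f)
        psd[np.abs(f - 0.05) < 0.0005] = 100.0 / 0.001
        psd[np.abs(f - 0.5) < 0.0005] = 50.0 / 0.001
        fd = sh.band_powers(Spectrum(f, psd, None))
        assert fd.lf_abs == pytest.approx(100.0, rel=0.01)
        assert fd.hf_abs == pytest.approx(50.0, rel=0.01)
        assert fd.vlf_abs == pytest.approx(0.0, abs=1e-9)
        assert fd.lf_pct == pytest.approx(66.67, abs=0.1)
        assert fd.lf_nu == pytest.approx(66.67, abs=0.1)
        assert fd.lf_hf == pytest.approx(2.0, rel=0.01)

    @given(st.integers(0, 2**32 - 1))
    @settings(derandomize=True, max_examples=50)
    def test_normalization_identities_on_random_spectra(self, seed):
        rng = np.random.default_rng(seed)
        f = np.linspace(0, 2.5, 400)
        psd = rng.exponential(10.0, len(f))
        fd = sh.band_powers(Spectrum(f, psd, None))
        assert fd.vlf_pct + fd.lf_pct + fd.hf_pct == pytest.approx(100.0, abs=1e-6)
        assert fd.lf_nu + fd.hf_nu == pytest.approx(100.0, abs=1e-6)

    def test_zero_hf_power_reports_undefined_ratio_not_infinity(self):
        f = np.linspace(0, 2.5, 400)
        # power only below 0.05 Hz so band-edge interpolation at 0.09 Hz is 0
        psd = np.where(f < 0.05, 10.0, 0.0)
        fd = sh.band_powers(Spectrum(f, psd, None))
        assert fd.lf_hf is None

    def test_end_to_end_sinusoid_band_recovery(self, lf_hf_rri):
        fd = sh.analyze_window(lf_hf_rri).freq
        assert fd.lf_abs == pytest.approx(200.0, rel=0.10)
        assert fd.hf_abs == pytest.approx(50.0, rel=0.10)
        assert fd.lf_hf == pytest.approx(4.0, rel=0.15)


class TestSpectralInvariants:
    def test_parseval_total_band_power_matches_tachogram_variance(self, lf_hf_rri):
        tach = sh.resample_tachogram(lf_hf_rri)
        fd = sh.band_powers(sh.estimate_psd(tach))
        assert fd.total_power == pytest.approx(np.var(tach.values), rel=0.05)

    def test_scaling_deviations_scales_powers_quadratically(self):
        rng = np.random.default_rng(5)
        dev = rng.normal(0, 20, 400)
        a = sh.time_domain(sh.RRISeries.from_nn(800 + dev))
        b = sh.time_domain(sh.RRISeries.from_nn(800 + 3 * dev))
        assert b.variance == pytest.approx(9 * a.variance, rel=1e-9)
        # spectral estimation is linear in the tachogram, so PSD (and band
        # powers) scale by the square while normalized quantities are invariant
        x = rng.normal(0, 15, 3000)
        fa = sh.band_powers(sh.estimate_psd(UniformTachogram(10.0, x)))
        fb = sh.band_powers(sh.estimate_psd(UniformTachogram(10.0, 3 * x)))
        assert fb.lf_abs == pytest.approx(9 * fa.lf_abs, rel=1e-9)
        assert fb.hf_abs == pytest.approx(9 * fa.hf_abs, rel=1e-9)
        assert fb.lf_nu == pytest.approx(fa.lf_nu, rel=1e-9)
        assert fb.lf_hf == pytest.approx(fa.lf_hf, rel=1e-9)

    def test_welch_and_lomb_agree_on_band_powers(self, lf_hf_rri):
        w = sh.analyze_window(lf_hf_rri, method="welch").freq
        l = sh.analyze_window(lf_hf_rri, method="lomb").freq
        assert l.lf_abs == pytest.approx(w.lf_abs, rel=0.10)
        assert l.hf_abs == pytest.approx(w.hf_abs, rel=0.20)

    def test_sdnn_squared_equals_variance(self, lf_hf_rri):
        td = sh.time_domain(lf_hf_rri)
        assert td.sdnn**2 == pytest.approx(td.variance, rel=1e-9)
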