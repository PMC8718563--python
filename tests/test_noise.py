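"""PSD computation, power-law fitting and the parabolic S(V) classification."""

import numpy as np
import pytest

from porekit import (SolutionCondition, Spectrum, TraceRecording,
                     VoltageProtocol, band_average, classify_fluctuations,
                     compute_psd, fit_noise_voltage, fit_spectral_exponent)


def _trace(x, fs):
    return TraceRecording(np.asarray(x, float), fs,
                          VoltageProtocol.constant(50.0, len(x) / fs),
                          SolutionCondition())


class TestComputePsd:
    def test_resolution_50khz_65536(self):
        """50 kHz sampling with 2^16-sample segments gives 0.76 Hz bins."""
        rng = np.random.default_rng(0)
        tr = _trace(rng.normal(0, 1, 2 * 65536), 50000.0)
        spec = compute_psd(tr, 65536, prefilter=None)
        assert round(spec.resolution, 2) == 0.76
        assert spec.resolution == pytest.approx(50000.0 / 65536, rel=1e-12)
        assert spec.n_segments == 2

    def test_bin_centered_sine_power(self):
        """Total band power of a bin-centered sinusoid is A^2/2 (Parseval)."""
        fs, n = 1000.0, 4096
        a = 3.0
        k = 64  # bin-centered frequency k*fs/n
        t = np.arange(n) / fs
        tr = _trace(a * np.sin(2 * np.pi * (k * fs / n) * t), fs)
        spec = compute_psd(tr, n, prefilter=None)
        total = spec.psd.sum() * spec.resolution
        assert total == pytest.approx(a ** 2 / 2, rel=1e-9)

    def test_white_noise_level(self):
        """Flat PSD ~ 2 sigma^2 / fs over the band (one-sided)."""
        fs, sigma = 2000.0, 1.5
        rng = np.random.default_rng(1)
        tr = _trace(rng.normal(0, sigma, 2 ** 18), fs)
        spec = compute_psd(tr, 4096, prefilter=None)
        assert spec.psd.mean() == pytest.approx(2 * sigma ** 2 / fs, rel=0.02)

    def test_parseval_conservation(self):
        """sum(psd) * df equals the mean per-segment variance within 1%."""
        rng = np.random.default_rng(2)
        tr = _trace(rng.normal(0, 1, 6 * 4096), 2000.0)
        spec = compute_psd(tr, 4096, prefilter=None)
        segs = tr.samples[:6 * 4096].reshape(6, 4096)
        var = ((segs - segs.mean(1, keepdims=True)) ** 2).mean()
        assert spec.psd.sum() * spec.resolution == pytest.approx(var, rel=1e-9)
        assert spec.psd.sum() * spec.resolution == pytest.approx(
            tr.samples.var(), rel=0.01)

    def test_band_halves_agree_within_segment_statistics(self):
        """Disjoint halves of a stationary trace give consistent S_lf."""
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 2 ** 17)
        fs, seg = 2000.0, 2048
        half = x.size // 2
        s1 = band_average(compute_psd(_trace(x[:half], fs), seg, prefilter=None))
        s2 = band_average(compute_psd(_trace(x[half:], fs), seg, prefilter=None))
        n_seg = half // seg
        n_bins = 9  # 1-10 Hz at ~1 Hz resolution
        rel_sd = 1 / np.sqrt(n_seg * n_bins)
        assert abs(s1 - s2) / s1 < 4 * np.sqrt(2) * rel_sd

    def test_segment_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            compute_psd(_trace(np.zeros(100), 1000.0), 200, prefilter=None)


class TestSpectralExponent:
    def _make_spectrum(self, f, s):
        return Spectrum(np.asarray(f, float), np.asarray(s, float),
                        float(f[1] - f[0]), 1)

    def test_exact_one_over_f(self):
        f = np.arange(1.0, 201.0)
        alpha, se = fit_spectral_exponent(self._make_spectrum(f, 1.0 / f),
                                          1.0, 200.0)
        assert alpha == pytest.approx(1.0, abs=1e-12)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_flat_spectrum(self):
        f = np.arange(1.0, 101.0)
        alpha, _ = fit_spectral_exponent(self._make_spectrum(f, np.ones(100)),
                                         1.0, 100.0)
        assert alpha == pytest.approx(0.0, abs=1e-12)

    def test_too_few_bins_rejected(self):
        f = np.arange(1.0, 6.0)
        with pytest.raises(ValueError):
            fit_spectral_exponent(self._make_spectrum(f, 1 / f), 1.0, 5.0)

    def test_nonpositive_psd_rejected(self):
        f = np.arange(1.0, 101.0)
        s = np.ones(100)
        s[10] = 0.0
        with pytest.raises(ValueError):
            fit_spectral_exponent(self._make_spectrum(f, s), 1.0, 100.0)


class TestBandAverage:
    def test_flat_value(self):
        f = np.arange(0.5, 50.0, 0.5)
        spec = Spectrum(f, np.full(f.size, 2.5), 0.5, 1)
        assert band_average(spec, 1.0, 10.0) == pytest.approx(2.5)

    def test_linear_psd_mean_of_bins(self):
        f = np.arange(1.0, 11.0)
        spec = Spectrum(f, f.copy(), 1.0, 1)
        assert band_average(spec, 1.0, 10.0) == pytest.approx(5.5)

    def test_empty_band_rejected(self):
        spec = Spectrum(np.arange(1.0, 11.0), np.ones(10), 1.0, 1)
        with pytest.raises(ValueError):
            band_average(spec, 100.0, 200.0)


class TestNoiseVoltageFit:
    def test_pure_parabola_through_origin(self):
        v = np.array([-50, -25, 0, 25, 50.0])
        curve = fit_noise_voltage(list(zip(v, 0.01 * v ** 2)))
        assert curve.a == pytest.approx(0.01, abs=1e-12)
        assert curve.c == pytest.approx(0.0, abs=1e-12)
        assert abs(curve.vertex) < 1e-9
        assert classify_fluctuations(curve) == "equilibrium"

    def test_parabola_with_offset(self):
        v = np.array([-50, -25, 0, 25, 50.0])
        curve = fit_noise_voltage(list(zip(v, 0.01 * v ** 2 + 0.5)))
        assert curve.a == pytest.approx(0.01, abs=1e-12)
        assert curve.c == pytest.approx(0.5, abs=1e-12)

    def test_linear_term_shifts_vertex(self):
        v = np.array([-50, -25, 0, 25, 50.0])
        curve = fit_noise_voltage(list(zip(v, 0.01 * v ** 2 + 0.2 * v)))
        assert curve.vertex == pytest.approx(-0.2 / (2 * 0.01), abs=1e-9)

    def test_quartic_data_classified_non_equilibrium(self):
        v = np.array([-50, -35, -20, 0, 20, 35, 50.0])
        curve = fit_noise_voltage(list(zip(v, 1e-6 * v ** 4)))
        assert classify_fluctuations(curve) == "non-equilibrium"

    def test_three_noisy_points_inconclusive(self):
        curve = fit_noise_voltage([(-50, 1.0), (0, 0.9), (50, 0.2)])
        assert classify_fluctuations(curve) == "inconclusive"

    def test_too_few_voltages_rejected(self):
        with pytest.raises(ValueError):
            fit_noise_voltage([(0, 1.0), (50, 2.0)])

    def test_polarity_symmetry_of_simulated_conductance_noise(self):
        """S_lf(+V)/S_lf(-V) ~ 1 when only conductance noise is present."""
        from porekit import SimConfig, simulate_pore_trace

        s = {}
        for v in (50.0, -50.0):
            cfg = SimConfig(baseline_conductance=2.0, insertion_rate=0.0,
                            retraction_rate=0.0,
                            conductance_noise_fraction=0.02,
                            noise_exponent=1.0, white_noise_rms=0.1,
                            sampling_rate=2000.0, analog_filter_cutoff=400.0,
                            duration=30.0, seed=21)
            tr = simulate_pore_trace(cfg, VoltageProtocol.constant(v, 30.0))
            s[v] = band_average(compute_psd(tr, 4096, prefilter=None))
        assert s[50.0] / s[-50.0] == pytest.approx(1.0, abs=0.2)

    def test_zero_voltage_trace_is_white_floor(self):
        """At V = 0 the PSD reduces to the white instrument floor."""
        from porekit import SimConfig, simulate_pore_trace

        cfg = SimConfig(baseline_conductance=2.0, insertion_rate=0.0,
                        retraction_rate=0.0, conductance_noise_fraction=0.05,
                        noise_exponent=1.0, white_noise_rms=1.0,
                        sampling_rate=2000.0, analog_filter_cutoff=400.0,
                        duration=30.0, seed=22)
        tr0 = simulate_pore_trace(cfg, VoltageProtocol.constant(0.0, 30.0))
        cfg_white = SimConfig(**{**cfg.__dict__, "conductance_noise_fraction": 0.0})
        trw = simulate_pore_trace(cfg_white, VoltageProtocol.constant(0.0, 30.0))
        s0 = band_average(compute_psd(tr0, 4096, prefilter=None))
        sw = band_average(compute_psd(trw, 4096, prefilter=None))
        assert s0 == pytest.approx(sw, rel=0.05)
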