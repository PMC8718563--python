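"""Simulator tests: colored noise spectra, current law, gating statistics."""

import numpy as np
import pytest

from porekit import (SimConfig, TraceRecording, VoltageProtocol,
                     generate_colored_noise, simulate_iv_dataset,
                     simulate_iv_points, simulate_pore_trace)
from porekit.noise import band_average, compute_psd, fit_spectral_exponent
from porekit.selectivity import reversal_potential_from_iv


class TestColoredNoise:
    def test_white_noise_limit(self):
        x = generate_colored_noise(65536, alpha=0.0, rms=1.0, seed=1)
        assert abs(x.mean()) < 0.05
        assert x.var() == pytest.approx(1.0, rel=0.02)

    def test_zero_rms_gives_zeros(self):
        assert not generate_colored_noise(1024, 1.0, 0.0, seed=2).any()

    def test_rms_is_exact(self):
        for alpha in (0.0, 0.9, 2.0):
            x = generate_colored_noise(4096, alpha, rms=2.5, seed=3)
            assert x.std() == pytest.approx(2.5, rel=1e-12)

    def test_deterministic_under_seed(self):
        a = generate_colored_noise(8192, 1.2, 1.0, seed=42)
        b = generate_colored_noise(8192, 1.2, 1.0, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_rejects_bad_args(self):
        with pytest.raises(ValueError):
            generate_colored_noise(1, 1.0, 1.0, 0)
        with pytest.raises(ValueError):
            generate_colored_noise(100, 2.5, 1.0, 0)

    @pytest.mark.parametrize("alpha", [0.5, 0.8, 1.0, 1.2])
    def test_spectral_exponent_recovered(self, alpha):
        """Fitted exponent over 1-100 Hz is unbiased within +/-0.1 (20 seeds)."""
        fits = []
        for seed in range(20):
            x = generate_colored_noise(2**17, alpha, 1.0, seed=seed)
            tr = TraceRecording(x, 2000.0,
                                VoltageProtocol.constant(0.0, x.size / 2000.0))
            spec = compute_psd(tr, 4096, prefilter=None)
            fits.append(fit_spectral_exponent(spec, 1.0, 100.0)[0])
        assert np.mean(fits) == pytest.approx(alpha, abs=0.1)


class TestSimulatePoreTrace:
    def test_ohmic_constant_pore(self, flat_pore_trace):
        """1 nS at +50 mV with no noise is a constant 50 pA line."""
        np.testing.assert_allclose(flat_pore_trace.samples, 50.0, rtol=1e-9)

    def test_trace_is_deterministic(self):
        cfg = SimConfig(insertion_rate=2.0, retraction_rate=2.0,
                        white_noise_rms=0.5, conductance_noise_fraction=0.01,
                        sampling_rate=2000.0, analog_filter_cutoff=400.0,
                        duration=2.0, seed=9)
        a = simulate_pore_trace(cfg)
        b = simulate_pore_trace(cfg)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_at_reversal_potential_only_white_noise(self):
        """V = V_rev: conductance fluctuations are invisible."""
        cfg = SimConfig(baseline_conductance=2.0, insertion_rate=1.0,
                        retraction_rate=1.0, conductance_noise_fraction=0.1,
                        white_noise_rms=0.4, reversal_potential=30.0,
                        sampling_rate=2000.0, analog_filter_cutoff=400.0,
                        duration=4.0, seed=5)
        tr = simulate_pore_trace(cfg, VoltageProtocol.constant(30.0, 4.0))
        assert abs(tr.samples.mean()) < 0.05
        # variance equals the (filtered) white floor: well below the raw RMS
        assert tr.samples.std() < cfg.white_noise_rms

    def test_mean_current_law(self):
        """<I> = G_total (V - V_rev) within 3 standard errors."""
        cfg = SimConfig(baseline_conductance=1.5, insertion_rate=0.0,
                        retraction_rate=0.0, conductance_noise_fraction=0.02,
                        white_noise_rms=0.5, reversal_potential=10.0,
                        sampling_rate=2000.0, analog_filter_cutoff=400.0,
                        duration=10.0, seed=6)
        tr = simulate_pore_trace(cfg, VoltageProtocol.constant(50.0, 10.0))
        expected = 1.5 * (50.0 - 10.0)
        se = tr.samples.std() / np.sqrt(tr.n_samples / 20)  # correlated samples
        assert abs(tr.samples.mean() - expected) < 3 * max(se, 0.05)

    def test_event_count_follows_insertion_rate(self):
        """Mean insertions over seeds ~ rate * duration (Poisson tolerance)."""
        rate, dur = 3.0, 10.0
        counts = []
        for seed in range(20):
            cfg = SimConfig(insertion_rate=rate, retraction_rate=0.0,
                            white_noise_rms=0.0, sampling_rate=2000.0,
                            analog_filter_cutoff=400.0, duration=dur, seed=seed)
            tr = simulate_pore_trace(cfg)
            ins = [e for e in tr.provenance["ground_truth"]["events"]
                   if e[1] > 0]
            counts.append(len(ins))
        mean_expected = rate * dur
        tol = 3 * np.sqrt(mean_expected / 20)
        assert np.mean(counts) == pytest.approx(mean_expected, abs=tol)

    def test_noise_stationarity_across_thirds(self):
        """Variance of disjoint thirds of a fixed-level trace agrees within 20%."""
        cfg = SimConfig(baseline_conductance=2.0, insertion_rate=0.0,
                        retraction_rate=0.0, white_noise_rms=1.0,
                        sampling_rate=2000.0, analog_filter_cutoff=400.0,
                        duration=15.0, seed=8)
        x = simulate_pore_trace(cfg).samples
        thirds = np.array_split(x, 3)
        vs = [t.var() for t in thirds]
        assert max(vs) / min(vs) < 1.2

    def test_protocol_shorter_than_duration_rejected(self):
        cfg = SimConfig(sampling_rate=2000.0, analog_filter_cutoff=400.0,
                        duration=2.0)
        with pytest.raises(ValueError):
            simulate_pore_trace(cfg, VoltageProtocol.constant(50.0, 1.0))

    def test_parabolic_noise_law_from_simulator(self):
        """Band-averaged 1-10 Hz noise vs V fits S = a V^2 + c, vertex ~ 0."""
        from porekit.noise import classify_fluctuations, fit_noise_voltage

        points = []
        for v in (-50.0, -25.0, 0.0, 25.0, 50.0):
            s = []
            for seed in range(3):
                cfg = SimConfig(baseline_conductance=2.0, insertion_rate=0.0,
                                retraction_rate=0.0,
                                conductance_noise_fraction=0.02,
                                noise_exponent=1.0, white_noise_rms=0.5,
                                sampling_rate=2000.0, analog_filter_cutoff=400.0,
                                duration=40.0, seed=300 + seed)
                tr = simulate_pore_trace(cfg, VoltageProtocol.constant(v, 40.0))
                s.append(band_average(compute_psd(tr, 4096, prefilter=None)))
            points.append((v, float(np.mean(s))))
        curve = fit_noise_voltage(points)
        assert curve.goodness >= 0.99
        assert abs(curve.vertex) <= 5.0
        assert classify_fluctuations(curve) == "equilibrium"


class TestIvDataset:
    def test_fixed_conductance_gives_ohmic_line(self):
        cfg = SimConfig(baseline_conductance=2.0, insertion_rate=0.0,
                        retraction_rate=0.0, white_noise_rms=0.2,
                        sampling_rate=2000.0, analog_filter_cutoff=400.0,
                        duration=1.0, seed=4)
        voltages = [-50, -30, -10, 10, 30, 50]
        traces = simulate_iv_dataset(cfg, voltages)
        iv = [(v, tr.samples.mean()) for v, tr in zip(voltages, traces)]
        rp, slope = reversal_potential_from_iv(iv)
        assert slope == pytest.approx(2.0, abs=0.02)
        assert rp == pytest.approx(0.0, abs=0.5)

    def test_zero_crossing_at_reversal_potential(self):
        pts = simulate_iv_points(2.0, 30.0, range(-10, 71, 10), 0.0, seed=0)
        rp, slope = reversal_potential_from_iv(pts)
        assert rp == pytest.approx(30.0, abs=1e-9)
        assert slope == pytest.approx(2.0, abs=1e-12)

    def test_rejects_single_voltage(self):
        cfg = SimConfig(sampling_rate=2000.0, analog_filter_cutoff=400.0)
        with pytest.raises(ValueError):
            simulate_iv_dataset(cfg, [50.0])
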