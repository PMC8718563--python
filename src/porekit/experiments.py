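"""Canned synthetic-recovery experiments.

Each function simulates data under stated study conditions with a known
ground truth, runs the corresponding analysis pipeline end to end, and
returns the recovered quantity averaged over independent seeds.  These are
the package's standard self-validation runs; the problem sizes are chosen
so each completes in seconds on one core.
"""

from __future__ import annotations

import numpy as np

from . import conductance as cond
from . import noise as noise_mod
from .selectivity import (SolutionCondition, analyze_selectivity,
                          ghk_reversal_potential, reversal_potential_from_iv)
from .synthetic import SimConfig, simulate_iv_points, simulate_pore_trace
from .trace import VoltageProtocol
from .trace_io import decimate

__all__ = [
    "recover_permeability_ratio",
    "recover_reversal_potential",
    "recover_minimal_unit",
    "recover_step_mode",
    "recover_spectral_exponent",
    "noise_voltage_curve",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31 - 1))
            for s in np.random.SeedSequence(seed).spawn(n)]


def recover_permeability_ratio(ratio: float, solution: SolutionCondition,
                               n_seeds: int = 20, seed: int = 0,
                               conductance: float = 3.0,
                               voltages=range(-50, 51, 10),
                               noise_fraction_of_span: float = 0.05
                               ) -> tuple[float, list[float]]:
    """Recover P+/P- from ohmic IV data through the GHK reversal potential.

    IV points are generated as I = G (V - V_rev(ratio)) with additive
    current noise whose SD is a fraction of the current span; the pipeline
    extracts the linear zero crossing and inverts the GHK equation.
    Returns (mean recovered ratio, per-seed values).
    """
    vrev = ghk_reversal_potential(ratio, solution)
    v = np.asarray(list(voltages), float)
    span = conductance * np.ptp(v)
    out = []
    for s in _child_seeds(seed, n_seeds):
        pts = simulate_iv_points(conductance, vrev, v,
                                 noise_fraction_of_span * span, s)
        out.append(analyze_selectivity(pts, solution, ljp=0.0)
                   .permeability_ratio)
    return float(np.mean(out)), out


def recover_reversal_potential(rp_true: float = 30.0, conductance: float = 3.0,
                               voltages=range(-10, 71, 10),
                               noise_sd: float = 5.0, n_seeds: int = 20,
                               seed: int = 0) -> tuple[float, list[float]]:
    """Mean fitted IV zero crossing (mV) over seeds for a noisy ohmic channel."""
    out = []
    for s in _child_seeds(seed, n_seeds):
        pts = simulate_iv_points(conductance, rp_true, voltages, noise_sd, s)
        out.append(reversal_potential_from_iv(pts)[0])
    return float(np.mean(out)), out


def _minimal_unit_once(unit_ns: float, voltage: float, seed: int,
                       white_noise_rms: float, duration: float) -> float:
    cfg = SimConfig(unit_conductance=unit_ns, insertion_rate=2.0,
                    retraction_rate=2.0, white_noise_rms=white_noise_rms,
                    sampling_rate=2000.0, analog_filter_cutoff=400.0,
                    duration=duration, seed=seed)
    tr = simulate_pore_trace(cfg, VoltageProtocol.constant(voltage, duration))
    trd = decimate(tr, 4)
    events = cond.detect_steps(trd)
    if not events:
        return float("nan")
    sd = cond._estimate_noise_sd(trd.samples)
    floor = 5.0 * sd / abs(voltage)
    g_hist, _dg = cond.build_g_dg_histograms(trd, events, min_abs=floor,
                                             seed=seed)
    return g_hist.minimal_unit


def recover_minimal_unit(unit_ps: float, voltage: float, n_seeds: int = 20,
                         seed: int = 0, white_noise_rms: float = 0.5,
                         duration: float = 50.0) -> tuple[float, list[float]]:
    """Lowest Gaussian-peak conductance (pS) from step-idealized unit-pore traces.

    Simulates ~200 insertion/retraction events of identical unit pores,
    idealizes the trace, histograms the absolute segment conductances,
    fits a mixture and reads the lowest component mean; sign-normalized, so
    it works identically at negative voltages.
    """
    vals = []
    for s in _child_seeds(seed, n_seeds):
        est = _minimal_unit_once(unit_ps / 1000.0, voltage, s,
                                 white_noise_rms, duration)
        vals.append(est * 1000.0)
    return float(np.nanmean(vals)), vals


def recover_step_mode(unit_ns: float = 0.1, baseline_ns: float = 3.0,
                      voltage: float = 70.0, mean_dwell: float = 0.2,
                      white_noise_rms: float = 1.0, duration: float = 20.0,
                      n_seeds: int = 20, seed: int = 0,
                      bin_width: float = 0.02) -> tuple[float, list[float]]:
    """Mode of |dG| (nS) for small events riding on a large stable pore."""
    vals = []
    for s in _child_seeds(seed, n_seeds):
        cfg = SimConfig(unit_conductance=unit_ns,
                        baseline_conductance=baseline_ns,
                        insertion_rate=0.5 / mean_dwell,
                        retraction_rate=1.0 / mean_dwell,
                        white_noise_rms=white_noise_rms,
                        sampling_rate=2000.0, analog_filter_cutoff=400.0,
                        duration=duration, seed=s)
        tr = simulate_pore_trace(cfg, VoltageProtocol.constant(voltage, duration))
        trd = decimate(tr, 4)
        events = cond.detect_steps(trd)
        if not events:
            vals.append(float("nan"))
            continue
        dg = np.array([e.delta_G for e in events])
        h = cond.build_conductance_histograms(dg, int(np.sign(voltage)),
                                              bin_width=bin_width)
        vals.append(h.mode())
    return float(np.nanmean(vals)), vals


def recover_spectral_exponent(alpha: float = 0.9, n_seeds: int = 20,
                              seed: int = 0, duration: float = 60.0
                              ) -> tuple[float, list[float]]:
    """Fitted 1/f^alpha exponent of simulated equilibrium-fluctuation traces."""
    vals = []
    for s in _child_seeds(seed, n_seeds):
        cfg = SimConfig(baseline_conductance=3.9, insertion_rate=0.0,
                        retraction_rate=0.0, conductance_noise_fraction=0.05,
                        noise_exponent=alpha, white_noise_rms=0.2,
                        sampling_rate=2000.0, analog_filter_cutoff=400.0,
                        duration=duration, seed=s)
        tr = simulate_pore_trace(cfg, VoltageProtocol.constant(50.0, duration))
        spec = noise_mod.compute_psd(tr, 4096, prefilter=None)
        vals.append(noise_mod.fit_spectral_exponent(spec, 1.0, 100.0)[0])
    return float(np.mean(vals)), vals


def noise_voltage_curve(voltages=(-50.0, -25.0, 0.0, 25.0, 50.0),
                        n_seeds: int = 4, seed: int = 0,
                        duration: float = 40.0) -> noise_mod.NoiseVoltageCurve:
    """Band-averaged 1-10 Hz noise vs voltage from pure conductance-noise traces.

    S_lf at each voltage is averaged over seeds before the parabolic fit.
    """
    all_seeds = iter(_child_seeds(seed, n_seeds * len(tuple(voltages))))
    points = []
    for v in voltages:
        s_acc = []
        for s in (next(all_seeds) for _ in range(n_seeds)):
            cfg = SimConfig(baseline_conductance=2.0, insertion_rate=0.0,
                            retraction_rate=0.0,
                            conductance_noise_fraction=0.02,
                            noise_exponent=1.0, white_noise_rms=0.5,
                            sampling_rate=2000.0, analog_filter_cutoff=400.0,
                            duration=duration, seed=s)
            tr = simulate_pore_trace(cfg, VoltageProtocol.constant(v, duration))
            s_acc.append(noise_mod.band_average(
                noise_mod.compute_psd(tr, 4096, prefilter=None)))
        points.append((v, float(np.mean(s_acc))))
    return noise_mod.fit_noise_voltage(points)
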