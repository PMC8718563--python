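"""Synthetic planar-bilayer current simulator.

Generates current recordings with known ground truth so that every analysis
stage (filtering, step idealization, histograms, PSD/noise analysis,
selectivity) can be validated without experimental data.  The current model
is

    I(t) = [G(t) + dG(t)] * (V(t) - V_rev) + white instrument noise,

where G(t) is the piecewise-constant conductance of a birth-death population
of identical unit pores (plus an optional permanent baseline pore), and
dG(t) is an equilibrium conductance-fluctuation term: a 1/f^alpha process
whose RMS is a fixed fraction of the instantaneous conductance.  Because the
fluctuation multiplies the driving force, the low-frequency current noise
power scales as (V - V_rev)^2 — the parabolic voltage dependence that
distinguishes equilibrium fluctuations from voltage-driven mechanisms such
as electroporation.

Randomness comes from one master seed split into fixed-order substreams
(gating, flicker, conductance noise, white noise), so identical configs give
bit-identical traces and adding one noise term never perturbs the draws of
another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from .trace import FilterSpec, SolutionCondition, TraceRecording, VoltageProtocol

__all__ = [
    "SimConfig",
    "generate_colored_noise",
    "simulate_pore_trace",
    "simulate_iv_dataset",
    "simulate_iv_points",
]

# substream order under the master seed; append-only so that adding a new
# noise source cannot perturb existing draws
_STREAMS = ("gating", "flicker", "conductance_noise", "white_noise", "iv_noise")


def _substream(seed: int, name: str, index: int = 0) -> np.random.Generator:
    k = _STREAMS.index(name)
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS) * (index + 1))
    return np.random.default_rng(children[len(_STREAMS) * index + k])


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters for :func:`simulate_pore_trace`.

    Parameters
    ----------
    unit_conductance : float
        Conductance of one unit pore, nS (tens of pS is typical of minimal
        peptide pores).
    baseline_conductance : float
        Permanent conductance present for the whole trace, nS (a stable
        large pore on which small unit events ride).
    level_multiplicities : sequence of int, optional
        If given, caps the pore count at max(level_multiplicities) and
        starts the population at the first entry; otherwise the count starts
        at 0 and is unbounded.
    insertion_rate, retraction_rate : float
        Birth-death kinetics, events/s.  Insertions arrive as a Poisson
        process at ``insertion_rate``; each open pore retracts independently
        at ``retraction_rate``.
    flicker_rates : (float, float), optional
        Rates (1/s) of open->sublevel and sublevel->open transitions of a
        telegraph process multiplying the pore conductance by
        ``flicker_sublevel`` while in the sublevel.
    flicker_sublevel : float
        Fractional conductance of the flicker sublevel (default 0.5).
    reversal_potential : float
        Zero-current voltage, mV.
    conductance_noise_fraction : float
        Relative RMS of the equilibrium conductance fluctuation dG.
    noise_exponent : float
        Spectral exponent alpha of the 1/f^alpha conductance fluctuation,
        in [0, 2].
    white_noise_rms : float
        RMS of the white instrument-noise floor, pA (before the analog
        filter).
    sampling_rate : float
        Acquisition sampling frequency, Hz.
    analog_filter_cutoff, analog_filter_poles :
        In-line Bessel low-pass emulating the acquisition chain; applied
        causally to the current before it is returned.
    duration : float
        Trace length, s.
    seed : int
        Master seed.
    """

    unit_conductance: float = 0.044
    baseline_conductance: float = 0.0
    level_multiplicities: tuple[int, ...] | None = None
    insertion_rate: float = 0.0
    retraction_rate: float = 0.0
    flicker_rates: tuple[float, float] | None = None
    flicker_sublevel: float = 0.5
    reversal_potential: float = 0.0
    conductance_noise_fraction: float = 0.0
    noise_exponent: float = 1.0
    white_noise_rms: float = 0.5
    sampling_rate: float = 50000.0
    analog_filter_cutoff: float = 10000.0
    analog_filter_poles: int = 8
    duration: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if min(self.insertion_rate, self.retraction_rate) < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.noise_exponent <= 2.0:
            raise ValueError("noise_exponent must lie in [0, 2]")
        if self.conductance_noise_fraction < 0 or self.white_noise_rms < 0:
            raise ValueError("noise amplitudes must be non-negative")
        if self.sampling_rate <= 2 * self.analog_filter_cutoff:
            raise ValueError("sampling_rate must exceed twice the analog filter cutoff")
        if self.level_multiplicities is not None:
            object.__setattr__(self, "level_multiplicities",
                               tuple(int(m) for m in self.level_multiplicities))


def generate_colored_noise(n: int, alpha: float, rms: float,
                           seed: int | np.random.Generator) -> np.ndarray:
    """Zero-mean Gaussian noise with a one-sided PSD proportional to f^-alpha.

    Synthesized spectrally: a white Gaussian spectrum is shaped by
    f^(-alpha/2) and inverse-transformed, then rescaled so the sample RMS
    equals ``rms`` exactly.  alpha=0 gives white noise.

    Parameters
    ----------
    n : int
        Number of samples (>= 2).
    alpha : float
        Spectral exponent in [0, 2].
    rms : float
        Target root-mean-square amplitude (same units as the output).
    seed : int or numpy Generator
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    if not 0.0 <= alpha <= 2.0:
        raise ValueError("alpha must lie in [0, 2]")
    if rms < 0:
        raise ValueError("rms must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nf = n // 2 + 1
    # draw in fixed order regardless of alpha so streams stay aligned
    re = rng.standard_normal(nf)
    im = rng.standard_normal(nf)
    if rms == 0.0:
        return np.zeros(n)
    f = np.fft.rfftfreq(n)  # cycles/sample; absolute scale cancels on rescale
    shape = np.zeros(nf)
    shape[1:] = f[1:] ** (-alpha / 2.0)
    spec = (re + 1j * im) * shape
    spec[0] = 0.0  # zero mean
    if n % 2 == 0:
        spec[-1] = spec[-1].real
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    if sd == 0.0:
        return np.zeros(n)
    return x * (rms / sd)


def _gillespie_pore_count(cfg: SimConfig, n: int, rng: np.random.Generator):
    """Sampled pore count N(t) plus the event log (time, +1/-1)."""
    if cfg.level_multiplicities:
        n0 = cfg.level_multiplicities[0]
        n_max = max(cfg.level_multiplicities)
    else:
        n0, n_max = 0, None
    t, count = 0.0, n0
    events: list[tuple[float, int]] = []
    lam, mu = cfg.insertion_rate, cfg.retraction_rate
    while True:
        r_in = lam if (n_max is None or count < n_max) else 0.0
        r_out = mu * count
        total = r_in + r_out
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t >= cfg.duration:
            break
        sign = 1 if rng.random() < r_in / total else -1
        count += sign
        events.append((t, sign))
    # per-sample count
    grid = np.zeros(n, dtype=float)
    grid[0] = n0
    delta = np.zeros(n)
    for et, sign in events:
        idx = int(np.ceil(et * cfg.sampling_rate))
        if idx < n:
            delta[idx] += sign
    counts = n0 + np.cumsum(delta)
    return counts, events


def _telegraph(n: int, fs: float, duration: float, rates: tuple[float, float],
               rng: np.random.Generator) -> np.ndarray:
    """0/1 state vector of a two-state Markov process starting in state 1 (open)."""
    k_down, k_up = rates
    state, t = 1, 0.0
    out = np.ones(n)
    while t < duration:
        rate = k_down if state == 1 else k_up
        if rate <= 0:
            break
        dt = rng.exponential(1.0 / rate)
        i0 = int(np.ceil((t + dt) * fs))
        state ^= 1
        if i0 >= n:
            break
        # fill from the switch on; later switches overwrite
        out[i0:] = state
        t += dt
    return out


def _acquisition_filter(x: np.ndarray, cfg: SimConfig) -> np.ndarray:
    sos = signal.bessel(cfg.analog_filter_poles,
                        cfg.analog_filter_cutoff, btype="low",
                        output="sos", norm="mag", fs=cfg.sampling_rate)
    zi = signal.sosfilt_zi(sos) * x[0]  # settled instrument: no startup step
    y, _ = signal.sosfilt(sos, x, zi=zi)
    return y


def simulate_pore_trace(config: SimConfig,
                        protocol: VoltageProtocol | None = None,
                        solution: SolutionCondition | None = None) -> TraceRecording:
    """Simulate one current recording.

    The returned trace's ``provenance["ground_truth"]`` carries the event
    log (times and signed conductance steps), the sampled level sequence
    parameters and all noise settings, for use as an oracle in tests.

    Raises
    ------
    ValueError
        If the protocol is shorter than ``config.duration``.
    """
    if protocol is None:
        protocol = VoltageProtocol.constant(50.0, config.duration)
    if solution is None:
        solution = SolutionCondition()
    if protocol.duration < config.duration - 1e-12:
        raise ValueError("voltage protocol shorter than the requested duration")

    n = int(round(config.duration * config.sampling_rate))
    if n < 2:
        raise ValueError("duration * sampling_rate must give at least 2 samples")
    t = np.arange(n) / config.sampling_rate
    v = protocol.voltage_at(t)
    drive = v - config.reversal_potential

    rng_gate = _substream(config.seed, "gating")
    rng_flick = _substream(config.seed, "flicker")
    rng_cond = _substream(config.seed, "conductance_noise")
    rng_white = _substream(config.seed, "white_noise")

    counts, events = _gillespie_pore_count(config, n, rng_gate)
    pore_g = counts * config.unit_conductance
    if config.flicker_rates is not None:
        gate = _telegraph(n, config.sampling_rate, config.duration,
                          config.flicker_rates, rng_flick)
        pore_g = pore_g * np.where(gate > 0, 1.0, config.flicker_sublevel)
    g_total = config.baseline_conductance + pore_g

    current = g_total * drive
    if config.conductance_noise_fraction > 0:
        x = generate_colored_noise(n, config.noise_exponent, 1.0, rng_cond)
        current = current + config.conductance_noise_fraction * g_total * x * drive
    if config.white_noise_rms > 0:
        current = current + rng_white.normal(0.0, config.white_noise_rms, n)
    current = _acquisition_filter(current, config)

    truth = {
        "unit_conductance_nS": config.unit_conductance,
        "baseline_conductance_nS": config.baseline_conductance,
        "reversal_potential_mV": config.reversal_potential,
        "noise_exponent": config.noise_exponent,
        "conductance_noise_fraction": config.conductance_noise_fraction,
        "white_noise_rms_pA": config.white_noise_rms,
        "events": [(float(et), float(sign * config.unit_conductance))
                   for et, sign in events],
        "initial_level_nS": float(config.baseline_conductance
                                  + counts[0] * config.unit_conductance),
        "final_level_nS": float(config.baseline_conductance
                                + counts[-1] * config.unit_conductance),
        "seed": config.seed,
    }
    prov = {
        "synthetic": True,
        "ground_truth": truth,
        "analog_filter": {"cutoff_hz": config.analog_filter_cutoff,
                          "poles": config.analog_filter_poles,
                          "family": "bessel"},
    }
    return TraceRecording(current, config.sampling_rate, protocol, solution, prov)


def simulate_iv_dataset(config: SimConfig, voltages: Sequence[float],
                        solution: SolutionCondition | None = None
                        ) -> list[TraceRecording]:
    """One trace per voltage with shared ground truth.

    Each voltage gets an independent noise substream derived from the master
    seed (stream index = position in ``voltages``); the conductance
    configuration (ground truth) is shared, emulating an IV protocol run on
    one stable insertion.
    """
    voltages = list(voltages)
    if len(set(voltages)) < 2:
        raise ValueError("need at least 2 distinct voltages")
    out = []
    children = np.random.SeedSequence(config.seed).spawn(len(voltages))
    for child, v in zip(children, voltages):
        sub = int(child.generate_state(1)[0] % (2**31 - 1))
        cfg_v = SimConfig(**{**config.__dict__, "seed": sub})
        out.append(simulate_pore_trace(
            cfg_v, VoltageProtocol.constant(v, config.duration), solution))
    return out


def simulate_iv_points(conductance: float, reversal_potential: float,
                       voltages: Sequence[float], noise_sd: float,
                       seed: int | np.random.Generator) -> np.ndarray:
    """Ohmic IV points I = G (V - V_rev) with additive Gaussian current noise.

    Returns an (n, 2) array of (V mV, I pA) — the minimal synthetic input
    for reversal-potential extraction.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v = np.asarray(list(voltages), dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 voltages")
    i = conductance * (v - reversal_potential) + rng.normal(0.0, noise_sd, v.size)
    return np.column_stack([v, i])
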