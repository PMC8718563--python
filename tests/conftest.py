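import numpy as np
import pytest

from porekit import SimConfig, VoltageProtocol, simulate_pore_trace


@pytest.fixture
def flat_pore_trace():
    """One permanent 1 nS pore at +50 mV, all noise off: constant 50 pA."""
    cfg = SimConfig(baseline_conductance=1.0, insertion_rate=0.0,
                    retraction_rate=0.0, conductance_noise_fraction=0.0,
                    white_noise_rms=0.0, sampling_rate=2000.0,
                    analog_filter_cutoff=400.0, duration=1.0, seed=0)
    return simulate_pore_trace(cfg, VoltageProtocol.constant(50.0, 1.0))


def make_step_trace(fs=1000.0, levels=(0.0, 2.5, 5.0, 2.5), seg_s=0.5,
                    noise_sd=0.0, voltage=50.0, seed=0):
    """Hand-built piecewise-constant current trace (pA) with optional noise."""
    from porekit import SolutionCondition, TraceRecording

    n_seg = int(seg_s * fs)
    x = np.concatenate([np.full(n_seg, lv) for lv in levels])
    if noise_sd > 0:
        x = x + np.random.default_rng(seed).normal(0, noise_sd, x.size)
    protocol = VoltageProtocol.constant(voltage, x.size / fs)
    return TraceRecording(x, fs, protocol, SolutionCondition(), {})
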