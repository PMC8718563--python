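"""Core containers for planar-bilayer current recordings.

Unit conventions used throughout the package: time in seconds, current in
pA, voltage in mV, conductance in nS (so ``I[pA] = G[nS] * V[mV]``),
concentration in mM, temperature in K.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np

__all__ = [
    "VoltageProtocol",
    "SolutionCondition",
    "FilterSpec",
    "TraceRecording",
]


@dataclass(frozen=True)
class VoltageProtocol:
    """Piecewise-constant applied-voltage protocol.

    Parameters
    ----------
    segments : sequence of (start_s, duration_s, voltage_mV)
        Constant-voltage epochs. Segments must be contiguous (each starts
        where the previous one ends), non-overlapping, and start at 0.
    """

    segments: tuple[tuple[float, float, float], ...]

    def __init__(self, segments: Sequence[Sequence[float]]):
        segs = tuple(tuple(float(x) for x in s) for s in segments)
        if not segs:
            raise ValueError("protocol needs at least one segment")
        t = 0.0
        for start, dur, _v in segs:
            if dur <= 0:
                raise ValueError("segment duration must be positive")
            if abs(start - t) > 1e-12 * max(1.0, abs(t)):
                raise ValueError("segments must be contiguous and start at 0")
            t = start + dur
        object.__setattr__(self, "segments", segs)

    @classmethod
    def constant(cls, voltage_mv: float, duration_s: float) -> "VoltageProtocol":
        return cls([(0.0, duration_s, voltage_mv)])

    @property
    def duration(self) -> float:
        start, dur, _ = self.segments[-1]
        return start + dur

    def voltage_at(self, t: np.ndarray | float) -> np.ndarray:
        """Voltage (mV) at time(s) ``t`` (s); right-open epochs."""
        t = np.asarray(t, dtype=float)
        starts = np.array([s[0] for s in self.segments])
        volts = np.array([s[2] for s in self.segments])
        idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(volts) - 1)
        return volts[idx]

    def is_constant(self) -> bool:
        return len({s[2] for s in self.segments}) == 1


@dataclass(frozen=True)
class SolutionCondition:
    """Bathing-solution metadata for a 1:1 electrolyte.

    ``c_cis``/``c_trans`` are salt concentrations (mM) on the peptide-addition
    (cis) and grounded (trans) sides.  The thermal voltage RT/F used by the
    selectivity formulas comes from ``temperature``.
    """

    c_cis: float = 150.0
    c_trans: float = 150.0
    salt: str = "KCl"
    temperature: float = 298.15
    activity_model: str = "ideal"

    def __post_init__(self):
        if self.c_cis <= 0 or self.c_trans <= 0:
            raise ValueError("concentrations must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.activity_model not in ("ideal", "davies", "user_table"):
            raise ValueError(f"unknown activity model {self.activity_model!r}")

    @property
    def gradient_ratio(self) -> float:
        return max(self.c_cis, self.c_trans) / min(self.c_cis, self.c_trans)


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Bessel filter specification (the electrophysiology standard).

    ``cutoff`` is the -3 dB frequency in Hz; ``poles`` the filter order.
    """

    cutoff: float
    poles: int = 8

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.poles not in (2, 4, 8):
            raise ValueError("poles must be one of 2, 4, 8")

    def rise_time(self) -> float:
        # 10-90% rise time of a Bessel low-pass, tr ~ 0.34 / f_c
        return 0.34 / self.cutoff


@dataclass
class TraceRecording:
    """A sampled current recording with its acquisition metadata.

    Attributes
    ----------
    samples : ndarray
        Current samples in pA.
    sampling_rate : float
        Sampling frequency in Hz.
    protocol : VoltageProtocol or None
        Applied-voltage protocol; None when the voltage is unknown.
    solution : SolutionCondition
    provenance : dict
        Free-form metadata: filter settings, simulation seed and ground
        truth when synthetic, source file when read from disk.
    """

    samples: np.ndarray
    sampling_rate: float
    protocol: VoltageProtocol | None = None
    solution: SolutionCondition = field(default_factory=SolutionCondition)
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def voltage(self) -> np.ndarray | None:
        if self.protocol is None:
            return None
        return self.protocol.voltage_at(self.times)

    def with_samples(self, samples: np.ndarray, sampling_rate: float | None = None,
                     **extra_provenance: Any) -> "TraceRecording":
        """Copy of this recording with new samples (and optional new rate)."""
        prov = dict(self.provenance)
        prov.update(extra_provenance)
        return TraceRecording(
            samples=np.asarray(samples, dtype=float),
            sampling_rate=self.sampling_rate if sampling_rate is None else sampling_rate,
            protocol=self.protocol,
            solution=self.solution,
            provenance=prov,
        )
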