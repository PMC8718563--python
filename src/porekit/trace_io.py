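"""Plain-text trace formats and the digital filtering applied before analysis.

Two dialects are supported: an Axon-Text-File-style tab-delimited format
(``#``-prefixed header lines, ``time_s`` and ``current_pA`` columns) and
plain CSV.  All numeric I/O is in s / pA / mV.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .trace import FilterSpec, SolutionCondition, TraceRecording, VoltageProtocol

__all__ = ["read_trace", "write_trace", "bessel_lowpass", "decimate",
           "write_ground_truth", "read_ground_truth"]

_HEADER_KEYS = ("sampling_rate_hz", "voltage_mv", "c_cis_mM", "c_trans_mM",
                "salt", "temperature_K")


def _delimiter(fmt: str) -> str:
    if fmt == "atf":
        return "\t"
    if fmt == "csv":
        return ","
    raise ValueError(f"unknown trace format {fmt!r} (use 'atf' or 'csv')")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "csv" if path.suffix.lower() == ".csv" else "atf"


def write_trace(trace: TraceRecording, path: str | Path,
                format: str | None = None, time_column: bool = True) -> Path:
    """Write a trace as ATF-style tab-delimited text or CSV.

    The header records sampling rate, applied voltage (for constant-voltage
    protocols) and solution metadata as ``# key: value`` lines.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    delim = _delimiter(fmt)
    sol = trace.solution
    lines = ["# porekit-trace v1",
             f"# sampling_rate_hz: {trace.sampling_rate!r}"]
    if trace.protocol is not None and trace.protocol.is_constant():
        lines.append(f"# voltage_mv: {trace.protocol.segments[0][2]!r}")
    lines += [f"# c_cis_mM: {sol.c_cis!r}", f"# c_trans_mM: {sol.c_trans!r}",
              f"# salt: {sol.salt}", f"# temperature_K: {sol.temperature!r}"]
    cols = ["time_s", "current_pA"] if time_column else ["current_pA"]
    lines.append(delim.join(cols))
    t = trace.times
    for k, i in enumerate(trace.samples):
        if time_column:
            lines.append(f"{t[k]:.9f}{delim}{float(i)!r}")
        else:
            lines.append(repr(float(i)))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_trace(path: str | Path, format: str | None = None) -> TraceRecording:
    """Read a trace written by :func:`write_trace` (or equivalent).

    The sampling rate is taken from the header; when absent it is recovered
    from the time column, which must be uniform to within 1 ppm.  A missing
    voltage produces a warning and a trace with ``protocol=None``.

    Raises
    ------
    ValueError
        On malformed headers, non-uniform time columns, or non-finite rows
        (the offending row is named).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    delim = _delimiter(fmt)
    header: dict[str, str] = {}
    rows_start = 0
    with open(path) as fh:
        lines = fh.read().splitlines()
    for k, line in enumerate(lines):
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                header[key.strip()] = val.strip()
        else:
            rows_start = k
            break
    df = pd.read_csv(path, sep=delim, comment="#", header=0)
    if "current_pA" not in df.columns:
        raise ValueError(f"{path}: malformed header, no 'current_pA' column")
    bad = ~np.isfinite(df["current_pA"].to_numpy(dtype=float))
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(f"{path}: non-finite current at data row {row}")

    if "sampling_rate_hz" in header:
        fs = float(header["sampling_rate_hz"])
    elif "time_s" in df.columns:
        t = df["time_s"].to_numpy(dtype=float)
        dt = np.diff(t)
        if dt.size == 0 or dt.min() <= 0:
            raise ValueError(f"{path}: cannot recover sampling rate from time column")
        if (dt.max() - dt.min()) > 1e-6 * dt.mean():
            raise ValueError(f"{path}: non-uniform time column (>1 ppm jitter)")
        fs = 1.0 / dt.mean()
    else:
        raise ValueError(f"{path}: no sampling rate in header and no time column")

    if "time_s" in df.columns:
        t = df["time_s"].to_numpy(dtype=float)
        if t.size > 1:
            dt = np.diff(t)
            if (dt.max() - dt.min()) > 1e-6 * max(dt.mean(), 1e-30):
                raise ValueError(f"{path}: non-uniform time column (>1 ppm jitter)")

    samples = df["current_pA"].to_numpy(dtype=float)
    n = samples.size
    protocol = None
    if "voltage_mv" in header:
        protocol = VoltageProtocol.constant(float(header["voltage_mv"]), n / fs)
    else:
        warnings.warn(f"{path}: no voltage in header; protocol unknown",
                      stacklevel=2)
    sol_kwargs = {}
    if "c_cis_mM" in header:
        sol_kwargs["c_cis"] = float(header["c_cis_mM"])
    if "c_trans_mM" in header:
        sol_kwargs["c_trans"] = float(header["c_trans_mM"])
    if "salt" in header:
        sol_kwargs["salt"] = header["salt"]
    if "temperature_K" in header:
        sol_kwargs["temperature"] = float(header["temperature_K"])
    solution = SolutionCondition(**sol_kwargs)
    return TraceRecording(samples, fs, protocol, solution,
                          {"source": str(path), "format": fmt})


def write_ground_truth(trace: TraceRecording, path: str | Path) -> Path:
    """Write the simulator's ground-truth sidecar (JSON) for a synthetic trace."""
    path = Path(path)
    truth = trace.provenance.get("ground_truth")
    if truth is None:
        raise ValueError("trace has no ground truth (not synthetic?)")
    path.write_text(json.dumps(truth, indent=1))
    return path


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _design_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    if spec.cutoff >= fs / 2:
        raise ValueError("filter cutoff must be below the Nyquist frequency")
    # analog Bessel prototype, bilinear transform with prewarping so the
    # magnitude response is exactly -3 dB at the cutoff (norm='mag')
    return signal.bessel(spec.poles, spec.cutoff, btype="low",
                         output="sos", norm="mag", fs=fs)


def bessel_lowpass(trace: TraceRecording, spec: FilterSpec) -> TraceRecording:
    """Causal Bessel low-pass (the digital analogue of the acquisition filter).

    Applied forward-only (not zero-phase), matching instrument behaviour;
    DC gain is 1 and the gain at ``spec.cutoff`` is -3 dB.
    """
    sos = _design_sos(spec, trace.sampling_rate)
    # start from the steady state for the first sample so a constant input
    # passes through unchanged (the instrument has settled long before the
    # recording starts)
    zi = signal.sosfilt_zi(sos) * trace.samples[0]
    y, _ = signal.sosfilt(sos, trace.samples, zi=zi)
    return trace.with_samples(y, digital_filter={"cutoff_hz": spec.cutoff,
                                                 "poles": spec.poles,
                                                 "family": "bessel"})


def decimate(trace: TraceRecording, factor: int) -> TraceRecording:
    """Reduce the sampling rate by an integer factor with anti-alias filtering.

    An 8-pole Bessel at 40% of the new Nyquist frequency is applied first;
    ``factor=1`` is the identity.
    """
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise ValueError("decimation factor must be an integer >= 1")
    if factor == 1:
        return trace
    new_fs = trace.sampling_rate / factor
    spec = FilterSpec(cutoff=0.4 * new_fs, poles=8)
    filt = bessel_lowpass(trace, spec)
    return trace.with_samples(filt.samples[::factor], sampling_rate=new_fs,
                              decimated_by=int(factor))
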