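"""Power-spectral-density analysis of open-pore current fluctuations.

Averaged one-sided PSDs from non-overlapping rectangular-window segments,
power-law (1/f^alpha) exponent fitting, low-frequency band averaging, and
the parabolic voltage-dependence test that discriminates equilibrium
conductance fluctuations (current noise power growing as V^2) from
voltage-driven mechanisms such as electroporation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .trace import FilterSpec, TraceRecording
from .trace_io import bessel_lowpass

__all__ = [
    "Spectrum",
    "NoiseVoltageCurve",
    "compute_psd",
    "fit_spectral_exponent",
    "band_average",
    "fit_noise_voltage",
    "classify_fluctuations",
]

DEFAULT_PREFILTER = FilterSpec(cutoff=1000.0, poles=8)


@dataclass(frozen=True)
class Spectrum:
    """One-sided PSD: ``psd`` in pA^2/Hz on ``frequencies`` (Hz).

    ``resolution`` is the bin spacing (sampling_rate / segment_length);
    ``n_segments`` the number of averaged segments.
    """
    frequencies: np.ndarray
    psd: np.ndarray
    resolution: float
    n_segments: int

    def to_csv(self, path) -> None:
        header = (f"# one-sided PSD, resolution_hz: {self.resolution!r}, "
                  f"n_segments: {self.n_segments}\nfrequency_hz,psd_pA2_per_hz")
        rows = "\n".join(f"{f!r},{p!r}" for f, p in zip(self.frequencies, self.psd))
        with open(path, "w") as fh:
            fh.write(header + "\n" + rows + "\n")


@dataclass(frozen=True)
class NoiseVoltageCurve:
    """Band-averaged low-frequency noise vs voltage with parabolic fits.

    ``a``/``c`` are from the vertex-at-zero fit S = a V^2 + c; ``vertex``
    comes from the unconstrained quadratic; ``goodness`` is the R^2 of the
    constrained fit.
    """
    points: tuple[tuple[float, float], ...]
    a: float
    c: float
    vertex: float
    goodness: float
    unconstrained: tuple[float, float, float]  # a, b, c of a V^2 + b V + c
    quartic_pvalue: float | None = None
    classification: str | None = None


def compute_psd(trace: TraceRecording, segment_length: int,
                prefilter: FilterSpec | str | None = "auto") -> Spectrum:
    """Averaged one-sided periodogram over non-overlapping segments.

    Each segment is mean-subtracted (rectangular window, no overlap) before
    the FFT; the DC bin is dropped.  Parseval holds: ``sum(psd) *
    resolution`` equals the mean per-segment variance of the (prefiltered)
    signal to machine precision.

    ``prefilter='auto'`` applies a 1 kHz 8-pole Bessel digital filter when
    the sampling rate allows it (> 2.5 kHz) and nothing otherwise; pass a
    :class:`FilterSpec` or ``None`` to override.
    """
    n = trace.n_samples
    if segment_length > n:
        raise ValueError("segment_length exceeds trace length")
    if segment_length < 2:
        raise ValueError("segment_length must be at least 2")
    if prefilter == "auto":
        prefilter = DEFAULT_PREFILTER if trace.sampling_rate > 2.5 * DEFAULT_PREFILTER.cutoff else None
    if prefilter is not None:
        trace = bessel_lowpass(trace, prefilter)
    fs = trace.sampling_rate
    n_seg = n // segment_length
    segs = trace.samples[:n_seg * segment_length].reshape(n_seg, segment_length)
    segs = segs - segs.mean(axis=1, keepdims=True)
    spec = np.fft.rfft(segs, axis=1)
    psd = (np.abs(spec) ** 2).mean(axis=0) * (2.0 / (fs * segment_length))
    if segment_length % 2 == 0:
        psd[-1] /= 2.0  # Nyquist bin is not doubled
    freqs = np.fft.rfftfreq(segment_length, d=1.0 / fs)
    return Spectrum(freqs[1:], psd[1:], fs / segment_length, n_seg)


def fit_spectral_exponent(spectrum: Spectrum, f_lo: float, f_hi: float
                          ) -> tuple[float, float]:
    """Exponent alpha of S(f) ~ f^-alpha by least squares on log S vs log f.

    Returns (alpha, standard error).  Requires >= 10 bins in the band and
    strictly positive PSD values there.
    """
    m = (spectrum.frequencies >= f_lo) & (spectrum.frequencies <= f_hi)
    if m.sum() < 10:
        raise ValueError("need at least 10 PSD bins in the fitting band")
    s = spectrum.psd[m]
    if np.any(s <= 0):
        raise ValueError("non-positive PSD values in the fitting band")
    res = stats.linregress(np.log(spectrum.frequencies[m]), np.log(s))
    return -float(res.slope), float(res.stderr)


def band_average(spectrum: Spectrum, f_lo: float = 1.0, f_hi: float = 10.0
                 ) -> float:
    """Arithmetic mean of the PSD bins with f_lo <= f <= f_hi (pA^2/Hz)."""
    m = (spectrum.frequencies >= f_lo) & (spectrum.frequencies <= f_hi)
    if not m.any():
        raise ValueError("no PSD bins in the requested band")
    return float(spectrum.psd[m].mean())


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = np.sum((y - yhat) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return float(1.0 - ss_res / ss_tot)


def fit_noise_voltage(points) -> NoiseVoltageCurve:
    """Fit S_lf(V) = a V^2 + c (vertex forced to 0) and the free quadratic.

    ``points`` is a sequence of (V mV, S_lf pA^2/Hz) with at least 3
    distinct voltages.  The reported vertex (-b/2a) comes from the
    unconstrained quadratic; goodness is the R^2 of the constrained fit.
    When >= 5 distinct voltages are available, an extra V^4 term is tested
    against the quadratic by an F-test, whose p-value feeds
    :func:`classify_fluctuations`.
    """
    pts = tuple((float(v), float(s)) for v, s in points)
    v = np.array([p[0] for p in pts])
    s = np.array([p[1] for p in pts])
    if np.unique(v).size < 3:
        raise ValueError("need at least 3 distinct voltages")
    # constrained: S = a V^2 + c
    A = np.column_stack([v ** 2, np.ones_like(v)])
    (a, c), *_ = np.linalg.lstsq(A, s, rcond=None)
    r2c = _r2(s, A @ np.array([a, c]))
    # unconstrained quadratic
    Aq = np.column_stack([v ** 2, v, np.ones_like(v)])
    coef_q, *_ = np.linalg.lstsq(Aq, s, rcond=None)
    aq, bq, cq = coef_q
    vertex = float(-bq / (2 * aq)) if aq != 0 else float("inf")
    # quartic alternative (nested F-test against the free quadratic)
    pval = None
    if np.unique(v).size >= 5 and v.size >= 5:
        A4 = np.column_stack([v ** 4, v ** 2, v, np.ones_like(v)])
        coef4, *_ = np.linalg.lstsq(A4, s, rcond=None)
        rss_q = float(np.sum((s - Aq @ coef_q) ** 2))
        rss_4 = float(np.sum((s - A4 @ coef4) ** 2))
        dof = v.size - 4
        if dof > 0 and rss_4 > 0:
            F = (rss_q - rss_4) / (rss_4 / dof)
            pval = float(stats.f.sf(max(F, 0.0), 1, dof))
        elif rss_4 == 0 and rss_q > 0:
            pval = 0.0
    return NoiseVoltageCurve(pts, float(a), float(c), vertex, r2c,
                             (float(aq), float(bq), float(cq)), pval)


def classify_fluctuations(curve: NoiseVoltageCurve,
                          r2_threshold: float = 0.95,
                          vertex_tolerance: float = 5.0,
                          quartic_alpha: float = 0.01) -> str:
    """Label the noise-voltage curve.

    ``equilibrium``: conductance-fluctuation signature — upward parabola
    (a > 0), good constrained fit (R^2 >= ``r2_threshold``) and vertex
    within ``vertex_tolerance`` mV of zero.  ``non-equilibrium``: the
    quadratic is rejected against the quartic alternative (F-test p below
    ``quartic_alpha``), as for voltage-driven mechanisms whose noise grows
    faster than V^2.  Anything else: ``inconclusive``.
    """
    if curve.quartic_pvalue is not None and curve.quartic_pvalue < quartic_alpha:
        label = "non-equilibrium"
    elif (curve.a > 0 and curve.goodness >= r2_threshold
          and abs(curve.vertex) <= vertex_tolerance):
        label = "equilibrium"
    else:
        label = "inconclusive"
    object.__setattr__(curve, "classification", label)
    return label
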