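"""Conductance-level statistics and step-event extraction.

Implements the single-channel workflow: all-points amplitude histograms,
Gaussian-mixture fits of current levels, conversion of levels to
conductances G = I/(V - V_rev), change-point idealization of step-wise
insertion/retraction events (signed conductance increments dG), and the
G / dG histograms with fitted peaks whose lowest mean identifies the
minimal conductive unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .trace import TraceRecording

__all__ = [
    "Histogram",
    "GaussianMixtureFit",
    "ConductanceEvent",
    "ConductanceHistogram",
    "all_points_histogram",
    "fit_gaussian_mixture",
    "conductance_from_levels",
    "detect_steps",
    "segment_levels",
    "build_conductance_histograms",
]


@dataclass(frozen=True)
class Histogram:
    """Simple binned histogram (edges in the units of the binned data)."""
    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def mean(self) -> float:
        tot = self.counts.sum()
        if tot == 0:
            return float("nan")
        return float(np.sum(self.centers * self.counts) / tot)


@dataclass(frozen=True)
class GaussianMixtureFit:
    """Result of a 1-D Gaussian mixture fit of current or conductance levels.

    ``components`` are (mean, sd, weight) triples sorted by mean; weights are
    positive and sum to 1.  ``selection_score`` is the BIC of the chosen
    model.  ``degenerate`` flags zero-variance input, for which a single
    delta component is reported.
    """
    components: tuple[tuple[float, float, float], ...]
    selection_score: float
    n_samples: int
    degenerate: bool = False

    @property
    def means(self) -> np.ndarray:
        return np.array([c[0] for c in self.components])

    @property
    def lowest_mean(self) -> float:
        return self.components[0][0]

    def standard_errors(self) -> np.ndarray:
        """Approximate SE of each component mean: sd / sqrt(weight * n)."""
        return np.array([sd / np.sqrt(max(w * self.n_samples, 1.0))
                         for _m, sd, w in self.components])


@dataclass(frozen=True)
class ConductanceEvent:
    """One step-wise insertion/retraction event.

    ``delta_G = post_level - pre_level`` (nS, signed); ``dwell_after`` is the
    time spent at ``post_level`` before the next event or end of trace.
    When the epoch voltage is unknown the 'conductances' are raw currents in
    pA (flagged by the caller).
    """
    time: float
    delta_G: float
    pre_level: float
    post_level: float
    dwell_after: float


@dataclass(frozen=True)
class ConductanceHistogram:
    """Binned conductances with Gaussian peaks; ``polarity`` is sign(V)."""
    bin_edges: np.ndarray
    counts: np.ndarray
    fitted_peaks: tuple[tuple[float, float], ...]  # (mean nS, sd nS)
    polarity: int
    mixture: GaussianMixtureFit | None = None

    @property
    def minimal_unit(self) -> float:
        """Mean of the lowest-conductance fitted peak (nS)."""
        if not self.fitted_peaks:
            return float("nan")
        return self.fitted_peaks[0][0]

    def mode(self) -> float:
        """Center of the most occupied bin."""
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return float(centers[np.argmax(self.counts)])


def all_points_histogram(trace: TraceRecording, bin_width: float) -> Histogram:
    """Histogram of every current sample (pA), the standard level display."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    x = trace.samples
    if x.size == 0:
        raise ValueError("empty trace")
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = np.ceil(x.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    nbins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(nbins + 1)
    counts, _ = np.histogram(x, bins=edges)
    return Histogram(edges, counts)


def fit_gaussian_mixture(samples: np.ndarray, k: int | str = "auto",
                         k_max: int = 5, seed: int = 0) -> GaussianMixtureFit:
    """Fit a 1-D Gaussian mixture; ``k='auto'`` selects components by BIC.

    Requires at least 50 samples.  Zero-variance input returns a flagged
    single delta component rather than failing.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 50:
        raise ValueError("need at least 50 samples for a mixture fit")
    if np.ptp(x) == 0.0:
        return GaussianMixtureFit(((float(x[0]), 0.0, 1.0),), float("nan"),
                                  x.size, degenerate=True)
    X = x.reshape(-1, 1)
    ks = range(1, k_max + 1) if k == "auto" else [int(k)]
    best = None
    for kk in ks:
        gm = GaussianMixture(n_components=kk, n_init=3, random_state=seed,
                             covariance_type="full").fit(X)
        bic = gm.bic(X)
        if best is None or bic < best[0]:
            best = (bic, gm)
    bic, gm = best
    comps = sorted(zip(gm.means_.ravel(),
                       np.sqrt(gm.covariances_.ravel()),
                       gm.weights_.ravel()))
    comps = tuple((float(m), float(s), float(w)) for m, s, w in comps)
    return GaussianMixtureFit(comps, float(bic), x.size)


def conductance_from_levels(fit: GaussianMixtureFit, voltage: float,
                            reversal_potential: float = 0.0) -> np.ndarray:
    """Conductances G = mean/(V - V_rev) (nS) per component, sign-normalized.

    Current levels are in pA and voltages in mV; conductance is reported
    positive regardless of voltage polarity.
    """
    drive = voltage - reversal_potential
    if drive == 0:
        raise ValueError("V equals the reversal potential: conductance undefined")
    return np.sort(np.abs(fit.means / drive))


# ---------------------------------------------------------------------------
# change-point idealization (PELT, L0-penalised piecewise-constant means)

def _pelt_mean(x: np.ndarray, penalty: float, min_size: int) -> list[int]:
    """Optimal changepoints of a piecewise-constant mean under an L0 penalty.

    Minimises sum of segment residual sums of squares + penalty * (#breaks)
    with PELT pruning; returns sorted interior breakpoints.
    """
    n = x.size
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def seg_cost(a: np.ndarray, b: int) -> np.ndarray:
        length = b - a
        su = s1[b] - s1[a]
        return (s2[b] - s2[a]) - su * su / length

    F = np.full(n + 1, np.inf)
    F[0] = -penalty
    last = np.zeros(n + 1, dtype=int)
    cand = np.array([0], dtype=int)
    for t in range(min_size, n + 1):
        ok = cand[t - cand >= min_size]
        if ok.size == 0:
            continue
        vals = F[ok] + seg_cost(ok, t) + penalty
        j = int(np.argmin(vals))
        F[t] = vals[j]
        last[t] = ok[j]
        keep = cand[F[cand] + seg_cost(cand, t) <= F[t]]
        cand = np.append(keep, t)
    # backtrack
    cps = []
    t = n
    while t > 0:
        s = last[t]
        if s == 0:
            break
        cps.append(int(s))
        t = s
    return sorted(cps)


def _estimate_noise_sd(x: np.ndarray) -> float:
    """Robust noise SD from the median absolute successive difference."""
    d = np.diff(x)
    if d.size == 0:
        return 0.0
    return float(np.median(np.abs(d)) / (0.6745 * np.sqrt(2.0)))


def detect_steps(trace: TraceRecording, penalty: float | None = None,
                 penalty_factor: float = 10.0,
                 min_dwell: float | None = None) -> list[ConductanceEvent]:
    """Idealize a trace into constant levels and return the step events.

    Change points are found by exact L0-penalised least squares (PELT); the
    default penalty is ``penalty_factor * sigma^2 * log(n)`` with ``sigma``
    estimated robustly from successive differences, so ``penalty_factor`` is
    the single sensitivity knob.  ``min_dwell`` (s) rejects segments shorter
    than twice the acquisition-filter rise time by default, to avoid counting
    filter edges as events.

    Events carry signed conductance increments dG (nS) computed with the
    epoch voltage; if the protocol is unknown they are reported in pA with a
    warning.

    A constant (noise-free flat) trace yields an empty list; noiseless step
    inputs are recovered exactly.
    """
    x = trace.samples
    n = x.size
    fs = trace.sampling_rate
    if min_dwell is None:
        cutoff = None
        filt = trace.provenance.get("digital_filter") or trace.provenance.get("analog_filter")
        if filt:
            cutoff = filt.get("cutoff_hz")
        if cutoff is None:
            cutoff = fs / 4.0
        min_dwell = 2 * 0.34 / cutoff
    min_size = max(2, int(round(min_dwell * fs)))
    if penalty is None:
        sd = _estimate_noise_sd(x)
        if sd == 0.0:
            penalty = 1e-12  # noiseless: any true step has positive cost gain
        else:
            penalty = penalty_factor * sd * sd * np.log(max(n, 2))
    cps = _pelt_mean(x, penalty, min_size)
    if not cps:
        return []

    voltage = None
    if trace.protocol is not None:
        v = trace.protocol.voltage_at((np.array(cps) - 0.5) / fs)
        v_rev = 0.0
        if trace.provenance.get("ground_truth"):
            v_rev = trace.provenance["ground_truth"].get("reversal_potential_mV", 0.0)
        drive = v - v_rev
        if np.any(drive == 0):
            voltage = None
        else:
            voltage = drive
    if voltage is None:
        warnings.warn("epoch voltage unknown or zero: step amplitudes reported "
                      "in pA, not nS", stacklevel=2)

    bounds = [0] + cps + [n]
    means = np.array([x[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])])
    events = []
    for i, cp in enumerate(cps):
        pre, post = means[i], means[i + 1]
        nxt = bounds[i + 2]
        if voltage is not None:
            pre, post = pre / voltage[i], post / voltage[i]
        events.append(ConductanceEvent(
            time=cp / fs,
            delta_G=float(post - pre),
            pre_level=float(pre),
            post_level=float(post),
            dwell_after=float((nxt - cp) / fs),
        ))
    return events


def segment_levels(trace: TraceRecording, events: list[ConductanceEvent]
                   ) -> np.ndarray:
    """Per-segment level values implied by an event list (initial level first).

    Units follow the events (nS when the voltage was known, else pA).
    """
    if not events:
        raise ValueError("no events")
    levels = [events[0].pre_level] + [e.post_level for e in events]
    return np.array(levels)


def build_conductance_histograms(values: np.ndarray, polarity: int,
                                 bin_width: float | None = None,
                                 min_abs: float = 0.0,
                                 k_max: int = 5, seed: int = 0
                                 ) -> ConductanceHistogram:
    """Histogram of conductances (nS) with Gaussian peaks fitted to it.

    ``values`` may be absolute level conductances (a G histogram) or step
    increments (a dG histogram); each entry counts once, regardless of its
    dwell.  ``min_abs`` drops values below a floor (e.g. the baseline/closed
    level); the lowest fitted peak is reported as the minimal conductive
    unit via :attr:`ConductanceHistogram.minimal_unit`.
    """
    g = np.abs(np.asarray(values, dtype=float).ravel())
    g = g[g >= min_abs]
    if g.size == 0:
        raise ValueError("no conductance values above the floor")
    if bin_width is None:
        bin_width = max(np.ptp(g) / 50.0, 1e-6)
    lo = np.floor(g.min() / bin_width) * bin_width
    nbins = max(1, int(np.ceil((g.max() - lo) / bin_width + 1e-9)))
    edges = lo + bin_width * np.arange(nbins + 1)
    counts, _ = np.histogram(g, bins=edges)
    mixture = None
    peaks: tuple[tuple[float, float], ...] = ()
    if g.size >= 50:
        mixture = fit_gaussian_mixture(g, "auto", k_max=k_max, seed=seed)
        peaks = tuple((m, s) for m, s, _w in mixture.components)
    elif g.size > 0:
        peaks = ((float(g.mean()), float(g.std())),)
    return ConductanceHistogram(edges, counts, peaks, int(np.sign(polarity)),
                                mixture)


def build_g_dg_histograms(trace: TraceRecording,
                          events: list[ConductanceEvent],
                          bin_width: float | None = None,
                          min_abs: float = 0.0, seed: int = 0
                          ) -> tuple[ConductanceHistogram, ConductanceHistogram]:
    """Paired absolute-conductance (G) and increment (dG) histograms.

    G values are the per-segment levels (excluding those below ``min_abs``,
    i.e. the closed state); dG values are the signed step sizes of the
    events, binned by magnitude.
    """
    if not events:
        raise ValueError("no events to histogram")
    pol = 0
    if trace.protocol is not None:
        pol = int(np.sign(trace.protocol.segments[0][2]))
    levels = segment_levels(trace, events)
    g_hist = build_conductance_histograms(levels, pol, bin_width,
                                          min_abs=min_abs, seed=seed)
    dg = np.array([e.delta_G for e in events])
    dg_hist = build_conductance_histograms(dg, pol, bin_width, seed=seed)
    return g_hist, dg_hist
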