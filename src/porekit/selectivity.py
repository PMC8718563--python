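"""Ion selectivity from reversal potentials under a salt gradient.

Workflow: extract the reversal potential (RP, the applied voltage that
cancels the current) from IV points by a linear zero-crossing fit, correct
it for the liquid-junction potentials of the electrode salt bridges
(Henderson equation), and convert RP to a cation/anion permeability ratio
P+/P- with the Goldman-Hodgkin-Katz (GHK) equation for a single 1:1 salt:

    V_rev = (RT/F) ln[(rho a_trans + a_cis) / (rho a_cis + a_trans)],

where rho = P+/P-, a is the salt activity on each side and V = V_cis -
V_trans (trans grounded; positive voltage on the peptide-addition side).
With the higher concentration on the trans side, a cation-selective pore
(rho > 1) gives a positive RP.  The inverse is algebraic:

    rho = (x a_trans - a_cis) / (a_trans - x a_cis),  x = exp(V_rev F / RT),

defined only for |V_rev| below the Nernst potential of the gradient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .trace import SolutionCondition

__all__ = [
    "SelectivityResult",
    "thermal_voltage",
    "reversal_potential_from_iv",
    "henderson_junction_potential",
    "two_bridge_correction",
    "ghk_reversal_potential",
    "ghk_permeability_ratio",
    "nernst_potential",
    "activity_coefficient",
    "analyze_selectivity",
    "MOBILITIES",
]

R_GAS = 8.31446261815324      # J / (mol K)
FARADAY = 96485.33212331      # C / mol

# limiting ionic mobilities u (m^2 V^-1 s^-1) at 25 C
MOBILITIES: dict[str, tuple[float, float]] = {
    "KCl": (7.619e-8, 7.909e-8),
    "NaCl": (5.193e-8, 7.909e-8),
    "LiCl": (4.010e-8, 7.909e-8),
}


def thermal_voltage(temperature: float = 298.15) -> float:
    """RT/F in mV (25.693 mV at 298.15 K)."""
    return R_GAS * temperature / FARADAY * 1e3


@dataclass(frozen=True)
class SelectivityResult:
    """Reversal potential and permeability ratio under a gradient.

    ``rp_corrected = rp_measured - ljp_correction``; ``permeability_ratio``
    is P+/P-.
    """
    rp_measured: float
    ljp_correction: float
    rp_corrected: float
    permeability_ratio: float
    gradient_ratio: float
    slope_conductance: float | None = None


def reversal_potential_from_iv(points) -> tuple[float, float]:
    """Zero crossing and slope of a least-squares line through IV points.

    ``points``: sequence of (V mV, I pA); the currents must bracket zero.
    Returns (rp mV, slope nS).
    """
    pts = np.asarray([(float(v), float(i)) for v, i in points])
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 IV points")
    v, i = pts[:, 0], pts[:, 1]
    if i.min() > 0 or i.max() < 0:
        raise ValueError("IV points do not bracket zero current")
    if np.ptp(v) == 0:
        raise ValueError("degenerate IV fit: all voltages equal")
    slope, intercept = np.polyfit(v, i, 1)
    if slope == 0:
        raise ValueError("degenerate IV fit: zero slope")
    return float(-intercept / slope), float(slope)


def henderson_junction_potential(bridge_conc: float, bath_conc: float,
                                 salt: str = "KCl",
                                 temperature: float = 298.15) -> float:
    """Single-junction Henderson potential (mV) of bath relative to bridge.

    For one 1:1 salt at two concentrations the Henderson equation reduces to

        E(bath) - E(bridge) = (RT/F) (u+ - u-)/(u+ + u-) ln(c_bridge/c_bath).

    KCl is near-equitransferent (u+ ~ u-), which is why concentrated-KCl
    bridges keep junction potentials near a millivolt.
    """
    if bridge_conc <= 0 or bath_conc <= 0:
        raise ValueError("concentrations must be positive")
    if salt not in MOBILITIES:
        raise ValueError(f"no mobility data for salt {salt!r}")
    u_plus, u_minus = MOBILITIES[salt]
    vt = thermal_voltage(temperature)
    return vt * (u_plus - u_minus) / (u_plus + u_minus) * math.log(bridge_conc / bath_conc)


def two_bridge_correction(solution: SolutionCondition,
                          bridge_conc: float = 2000.0) -> float:
    """Net liquid-junction correction (mV) for identical bridges in both baths.

    The measured potential contains the cis-side junction minus the
    trans-side junction; this difference is subtracted from the measured RP.
    """
    e_cis = henderson_junction_potential(bridge_conc, solution.c_cis,
                                         solution.salt, solution.temperature)
    e_trans = henderson_junction_potential(bridge_conc, solution.c_trans,
                                           solution.salt, solution.temperature)
    return e_cis - e_trans


def activity_coefficient(c: float, model: str = "ideal",
                         table: dict[float, float] | None = None,
                         temperature: float = 298.15) -> float:
    """Mean activity coefficient of a 1:1 salt at concentration ``c`` (mM).

    ``ideal`` returns 1; ``davies`` evaluates the Davies equation
    (log10 gamma = -A [sqrt(I)/(1+sqrt(I)) - 0.3 I], A = 0.509 at 25 C, I in
    mol/L); ``user_table`` interpolates a {mM: gamma} table linearly and
    fails outside its range.
    """
    if c <= 0:
        raise ValueError("concentration must be positive")
    if model == "ideal":
        return 1.0
    if model == "davies":
        ionic = c / 1000.0  # mol/L, 1:1 salt
        sq = math.sqrt(ionic)
        return 10.0 ** (-0.509 * (sq / (1 + sq) - 0.3 * ionic))
    if model == "user_table":
        if not table:
            raise ValueError("user_table model needs a table")
        xs = sorted(table)
        if not xs[0] <= c <= xs[-1]:
            raise ValueError(f"concentration {c} mM outside table range")
        return float(np.interp(c, xs, [table[x] for x in xs]))
    raise ValueError(f"unknown activity model {model!r}")


def _activities(solution: SolutionCondition,
                table: dict[float, float] | None = None) -> tuple[float, float]:
    g_cis = activity_coefficient(solution.c_cis, solution.activity_model,
                                 table, solution.temperature)
    g_trans = activity_coefficient(solution.c_trans, solution.activity_model,
                                   table, solution.temperature)
    return g_cis * solution.c_cis, g_trans * solution.c_trans


def nernst_potential(solution: SolutionCondition,
                     table: dict[float, float] | None = None) -> float:
    """RP limit (mV) of a perfectly cation-selective pore: (RT/F) ln(a_t/a_c)."""
    a_cis, a_trans = _activities(solution, table)
    return thermal_voltage(solution.temperature) * math.log(a_trans / a_cis)


def ghk_reversal_potential(ratio: float, solution: SolutionCondition,
                           table: dict[float, float] | None = None) -> float:
    """GHK reversal potential (mV) for permeability ratio rho = P+/P-."""
    if ratio <= 0:
        raise ValueError("permeability ratio must be positive")
    a_cis, a_trans = _activities(solution, table)
    vt = thermal_voltage(solution.temperature)
    return vt * math.log((ratio * a_trans + a_cis) / (ratio * a_cis + a_trans))


def ghk_permeability_ratio(rp_corrected: float, solution: SolutionCondition,
                           table: dict[float, float] | None = None) -> float:
    """Exact algebraic inverse of :func:`ghk_reversal_potential`.

    Raises
    ------
    ValueError
        When |rp| reaches the Nernst potential of the gradient (no finite
        ratio exists); the bound is reported in the message.
    """
    a_cis, a_trans = _activities(solution, table)
    vt = thermal_voltage(solution.temperature)
    x = math.exp(rp_corrected / vt)
    denom = a_trans - x * a_cis
    numer = x * a_trans - a_cis
    if denom <= 0 or numer <= 0:
        bound = vt * abs(math.log(a_trans / a_cis))
        raise ValueError(
            f"|RP| = {abs(rp_corrected):.3f} mV is at or beyond the Nernst "
            f"bound {bound:.3f} mV for this gradient: no finite ratio")
    return numer / denom


def analyze_selectivity(iv_points, solution: SolutionCondition,
                        ljp: float | str = "auto",
                        bridge_conc: float = 2000.0,
                        table: dict[float, float] | None = None
                        ) -> SelectivityResult:
    """Full RP -> P+/P- pipeline on an IV dataset.

    ``ljp='auto'`` applies the two-bridge Henderson correction; pass a
    number (mV) to override it manually, or 0 to skip.
    """
    rp, slope = reversal_potential_from_iv(iv_points)
    correction = (two_bridge_correction(solution, bridge_conc)
                  if ljp == "auto" else float(ljp))
    rp_corr = rp - correction
    ratio = ghk_permeability_ratio(rp_corr, solution, table)
    return SelectivityResult(rp_measured=rp, ljp_correction=correction,
                             rp_corrected=rp_corr, permeability_ratio=ratio,
                             gradient_ratio=solution.gradient_ratio,
                             slope_conductance=slope)
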