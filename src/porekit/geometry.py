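"""Conductance-based pore sizing.

A water-filled pore of radius r and length L in an electrolyte of bulk
conductivity kappa has, to first order, the conductance of a conducting
cylinder, G = kappa pi r^2 / L.  With r in nm, L in nm and kappa in S/m
this expression conveniently yields G directly in nS.  An optional
access-resistance variant adds the convergence resistance of the two pore
mouths, 1/(2 kappa r) per Hall, giving 1/G = L/(kappa pi r^2) + 1/(2 kappa r);
for the same measured G it returns a larger radius, which matters for short
wide pores.  This variant is an extension beyond the bare cylinder
estimate and is labelled as such in every result.

Because bulk conductivity inside a nanoscale pore can differ from the bath,
sizing by formula is rough; ``compare_reference_channels`` instead brackets
a measured conductance between channels of known radius recorded in the
same electrolyte and interpolates on a log-log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "PoreGeometry",
    "ReferenceChannelTable",
    "ReferenceComparison",
    "radius_from_conductance",
    "conductance_from_radius",
    "compare_reference_channels",
    "DEFAULT_KAPPA",
    "DEFAULT_LENGTH",
    "REFERENCE_RADII",
]

DEFAULT_KAPPA = 1.8   # S/m, 150 mM KCl at pH 7.4
DEFAULT_LENGTH = 4.0  # nm, typical lipid bilayer thickness

# Radii (nm) of channels commonly used as conductance yardsticks in
# negatively charged membranes; conductances are deliberately not shipped —
# they depend on electrolyte and must be supplied by the user.
REFERENCE_RADII: dict[str, float] = {
    "gA": 0.4,
    "ALA-L0": 0.75,
    "ALA-L1": 1.2,
    "VDAC": 1.25,
    "OmpF": 1.0,
}

_MODELS = ("cylinder", "cylinder+access")


@dataclass(frozen=True)
class PoreGeometry:
    """A radius estimate with the model and constants that produced it."""
    radius: float      # nm
    model: str
    kappa: float       # S/m
    length: float      # nm
    conductance: float  # nS

    def __post_init__(self):
        if self.radius < 0 or self.kappa <= 0 or self.length <= 0:
            raise ValueError("invalid geometry parameters")
        if self.model not in _MODELS:
            raise ValueError(f"unknown model {self.model!r}")


@dataclass(frozen=True)
class ReferenceChannelTable:
    """(name, conductance nS, radius nm) entries sorted by conductance."""
    entries: tuple[tuple[str, float, float], ...]

    def __init__(self, entries):
        ents = tuple(sorted(((str(n), float(g), float(r)) for n, g, r in entries),
                            key=lambda e: e[1]))
        if not ents:
            raise ValueError("reference table is empty")
        if any(r <= 0 or g <= 0 for _n, g, r in ents):
            raise ValueError("reference conductances and radii must be positive")
        object.__setattr__(self, "entries", ents)


@dataclass(frozen=True)
class ReferenceComparison:
    lower: tuple[str, float, float] | None
    upper: tuple[str, float, float] | None
    radius: float
    extrapolated: bool


def conductance_from_radius(radius: float, kappa: float = DEFAULT_KAPPA,
                            length: float = DEFAULT_LENGTH,
                            model: str = "cylinder") -> float:
    """Pore conductance (nS) for radius r (nm).

    cylinder: G = kappa pi r^2 / L.  cylinder+access: strictly smaller for
    the same r because of the series mouth resistances.
    """
    if radius < 0 or kappa <= 0 or length <= 0:
        raise ValueError("radius must be >= 0; kappa and length positive")
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}")
    if radius == 0:
        return 0.0
    g_cyl = kappa * math.pi * radius ** 2 / length
    if model == "cylinder":
        return g_cyl
    g_access = 2.0 * kappa * radius
    return 1.0 / (1.0 / g_cyl + 1.0 / g_access)


def radius_from_conductance(conductance: float, kappa: float = DEFAULT_KAPPA,
                            length: float = DEFAULT_LENGTH,
                            model: str = "cylinder") -> PoreGeometry:
    """Pore radius (nm) from a measured conductance (nS).

    cylinder: closed form r = sqrt(G L / (kappa pi)).  cylinder+access:
    bracketed root of 1/G = L/(kappa pi r^2) + 1/(2 kappa r); always at
    least the cylinder radius.  Round trip with
    :func:`conductance_from_radius` is exact to 1e-9 relative.
    """
    if conductance < 0:
        raise ValueError("conductance must be non-negative")
    if kappa <= 0 or length <= 0:
        raise ValueError("kappa and length must be positive")
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}")
    if conductance == 0.0:
        return PoreGeometry(0.0, model, kappa, length, 0.0)
    r_cyl = math.sqrt(conductance * length / (kappa * math.pi))
    if model == "cylinder":
        return PoreGeometry(r_cyl, model, kappa, length, conductance)

    def err(r: float) -> float:
        return conductance_from_radius(r, kappa, length, model) - conductance

    lo, hi = r_cyl, 2.0 * r_cyl
    while err(hi) < 0:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("no positive root for access-corrected radius")
    root = brentq(err, lo, hi, xtol=1e-15, rtol=1e-14)
    return PoreGeometry(float(root), model, kappa, length, conductance)


def compare_reference_channels(conductance: float,
                               table: ReferenceChannelTable
                               ) -> ReferenceComparison:
    """Bracket a conductance between reference channels of known radius.

    Returns the two bracketing entries and a log-log interpolated radius;
    outside the table range the nearest entry's radius is returned with
    ``extrapolated=True``.
    """
    if conductance <= 0:
        raise ValueError("conductance must be positive")
    ents = table.entries
    gs = np.array([g for _n, g, _r in ents])
    for ent in ents:
        if math.isclose(ent[1], conductance, rel_tol=1e-12):
            return ReferenceComparison(ent, ent, ent[2], False)
    if conductance < gs[0]:
        return ReferenceComparison(None, ents[0], ents[0][2], True)
    if conductance > gs[-1]:
        return ReferenceComparison(ents[-1], None, ents[-1][2], True)
    idx = int(np.searchsorted(gs, conductance)) - 1
    lo, hi = ents[idx], ents[idx + 1]
    frac = (math.log(conductance) - math.log(lo[1])) / (math.log(hi[1]) - math.log(lo[1]))
    radius = math.exp(math.log(lo[2]) + frac * (math.log(hi[2]) - math.log(lo[2])))
    return ReferenceComparison(lo, hi, radius, False)
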