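"""Hyperbolic-tangent model of overlapping membrane footprints.

A curved membrane protein (here the Piezo dome) deforms the surrounding
bilayer into a "footprint" that decays towards the flat bulk membrane.
The footprint profile is modelled as an ansatz

    h(x) = tanh(m0 * x),        m0 = tan(alpha),

in reduced units (lengths scaled by the footprint height H), where
``alpha`` is the inclination angle of the protein arms at the dome edge
and ``x`` is the radial distance from the dome edge.  When two domes sit
a reduced distance D = R/H apart, their footprints meet midway (x = D/2)
at an intersection angle

    theta = pi - 2*arctan(m_intersect),
    m_intersect = m0 * sech^2(m0 * D/2).

theta(alpha; D) is biphasic in alpha: for each D there is a critical
inclination where theta is minimal, equivalently for each alpha a
critical separation D_crit at which that alpha is the stationary point.
D_crit solves

    tan(alpha) * D * tanh(tan(alpha) * D/2) = 1,

obtained by differentiating theta with respect to alpha.  The physical
critical dome-dome distance is R_crit = D_crit * H.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .constants import TENSION_AREA_TO_ZJ, kbt_zj

__all__ = [
    "FootprintGeometry",
    "OverlapResult",
    "FreeEnergyTerms",
    "footprint_height",
    "intersection_angle",
    "critical_D",
    "critical_R",
    "opening_free_energy",
    "theta_curve",
]


def _check_alpha(alpha: float) -> None:
    if not 0.0 <= alpha < math.pi / 2:
        raise ValueError(f"alpha must lie in [0, pi/2); got {alpha!r}")


@dataclass(frozen=True)
class FootprintGeometry:
    """Reduced-unit description of a dome/footprint pair.

    Parameters
    ----------
    alpha : float
        Arm inclination angle against the membrane plane, radians.
    H : float
        Dome-to-bulk-midplane footprint height, nm.
    R : float
        Dome-dome edge separation, nm.
    """

    alpha: float
    H: float
    R: float
    D: float = field(init=False)
    m0: float = field(init=False)

    def __post_init__(self) -> None:
        _check_alpha(self.alpha)
        if self.H <= 0:
            raise ValueError("footprint height H must be positive")
        if self.R < 0:
            raise ValueError("separation R must be non-negative")
        object.__setattr__(self, "D", self.R / self.H)
        object.__setattr__(self, "m0", math.tan(self.alpha))


@dataclass(frozen=True)
class OverlapResult:
    """Footprint slope and intersection angle where two footprints meet."""

    m_intersect: float
    theta: float  # radians, in (0, pi]


@dataclass(frozen=True)
class FreeEnergyTerms:
    """Free-energy balance of pore opening with footprint overlap.

    All energies in kBT; ``gamma`` is membrane tension in mN/m and
    ``dA`` the projected in-plane area change in nm^2.
    """

    dG_protein: float
    dG_memb: float
    dG_overlap: float
    gamma: float = 0.0
    dA: float = 0.0


def footprint_height(x, alpha: float):
    """Reduced membrane height tanh(tan(alpha)*x) at reduced distance x.

    x may be a scalar or array; x >= 0 required.
    """
    _check_alpha(alpha)
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("radial distance x must be non-negative")
    out = np.tanh(math.tan(alpha) * x)
    return float(out) if out.ndim == 0 else out


def _sech2(y):
    # overflow-safe sech^2: (2 e^-|y| / (1 + e^-2|y|))^2
    e = np.exp(-np.abs(y))
    return (2.0 * e / (1.0 + e * e)) ** 2


def intersection_angle(alpha: float, D: float, form: str = "canonical") -> OverlapResult:
    """Angle at which two overlapping footprints meet, midway between domes.

    ``form='canonical'`` uses theta = pi - 2*arctan(m_intersect) (the
    geometric construction: pi minus the two inclination angles at the
    intersection).  ``form='literal'`` uses the alternative reading
    theta = pi - 2*arctan(tan(alpha)) * sech^2(tan(alpha)*D/2), kept for
    cross-checking; the canonical form is the default.
    """
    _check_alpha(alpha)
    if D < 0:
        raise ValueError("separation D must be non-negative")
    t = math.tan(alpha)
    m = t * _sech2(t * D / 2.0)
    if form == "canonical":
        theta = math.pi - 2.0 * math.atan(m)
    elif form == "literal":
        theta = math.pi - 2.0 * math.atan(t) * _sech2(t * D / 2.0)
    else:
        raise ValueError(f"unknown form {form!r}")
    return OverlapResult(m_intersect=float(m), theta=float(theta))


def _stationarity(D: float, t: float) -> float:
    return t * D * math.tanh(t * D / 2.0) - 1.0


def critical_D(alpha: float, form: str = "canonical") -> float:
    """Critical separation coefficient D at which ``alpha`` is the
    stationary point of theta(alpha; D).

    For the canonical theta the condition reduces to
    tan(alpha)*D*tanh(tan(alpha)*D/2) = 1, solved by bracketed bisection
    (the left side is monotone increasing in D).  For the literal form
    the stationarity of theta in alpha is solved numerically from a
    central-difference derivative.
    """
    if not 0.0 < alpha < math.pi / 2:
        raise ValueError("alpha must lie strictly in (0, pi/2) for a finite root")
    t = math.tan(alpha)
    if form == "canonical":
        lo, hi = 1e-6, 100.0
        if _stationarity(hi, t) < 0:
            raise ValueError("no root in bracket (alpha too small)")
        return float(brentq(lambda D: _stationarity(D, t), lo, hi, xtol=1e-10))
    if form == "literal":
        # d theta/d alpha = 0 for the literal theta reduces to
        # D*(1+t^2)*arctan(t)*tanh(t*D/2) = 1, again monotone in D
        def g(D: float) -> float:
            return D * (1 + t**2) * math.atan(t) * math.tanh(t * D / 2.0) - 1.0

        if g(100.0) < 0:
            raise ValueError("no root in bracket (alpha too small)")
        return float(brentq(g, 1e-6, 100.0, xtol=1e-10))
    raise ValueError(f"unknown form {form!r}")


def critical_R(alpha: float, H: float, form: str = "canonical") -> float:
    """Critical dome-dome distance R_crit = D_crit(alpha) * H, nm."""
    if H <= 0:
        raise ValueError("footprint height H must be positive")
    return critical_D(alpha, form=form) * H


def opening_free_energy(terms: FreeEnergyTerms, temperature_k: float = 310.15) -> float:
    """Net free energy of opening, kBT.

    dG_total = dG_protein - (dG_memb + dG_overlap) - gamma*dA, where the
    tension work gamma*dA (mN/m * nm^2 = zJ) is converted to kBT once,
    at the given temperature (default 310.15 K).
    """
    for name in ("dG_protein", "dG_memb", "dG_overlap", "gamma", "dA"):
        v = getattr(terms, name)
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite")
    tension_kbt = terms.gamma * terms.dA * TENSION_AREA_TO_ZJ / kbt_zj(temperature_k)
    return terms.dG_protein - (terms.dG_memb + terms.dG_overlap) - tension_kbt


def theta_curve(alpha: float, D_values) -> np.ndarray:
    """theta(alpha; D) over an array of separations, radians."""
    return np.array([intersection_angle(alpha, D).theta for D in np.asarray(D_values, float)])
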