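"""Forward model of C4 leaf photosynthesis.

Net CO2 assimilation A of a C4 leaf is the minimum of an enzyme-limited
rate (Rubisco carboxylation in the bundle sheath, fed by PEP carboxylation
in the mesophyll) and an electron-transport-limited rate (chloroplast ATP
supply shared between the C4 and C3 cycles).  Both branches are coupled to
CO2 supply: mesophyll CO2 (Cm) is drawn down from intercellular CO2 by the
assimilation flux through the mesophyll conductance gm, and bundle-sheath
CO2 (Cs) is set by the balance between C4-acid decarboxylation and leakage
through the bundle-sheath conductance gbs.  Because A appears on both the
supply and demand sides, each branch is a scalar fixed-point problem in A,
solved here by bracketed root finding.

Units follow gas-exchange convention: rates in umol m-2 s-1, CO2 partial
pressures in ubar, O2 in mbar, conductances in mol m-2 s-1 bar-1.  CO2 mole
fractions (ppm) are treated as numerically equal to ubar (1 bar total
pressure).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, NamedTuple

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "C4Constants",
    "LeafPhotoParams",
    "LeafEnvironment",
    "ConvergenceError",
    "NonPhysicalWarning",
    "electron_transport_rate",
    "enzyme_limited_A",
    "light_limited_A",
    "net_assimilation",
    "predict_curve",
]


class ConvergenceError(RuntimeError):
    """No self-consistent assimilation rate in the physical bracket."""


class NonPhysicalWarning(UserWarning):
    """The solution implies a non-physical state (e.g. Cm <= 0)."""


@dataclass(frozen=True)
class C4Constants:
    """Enzymatic and anatomical constants of the C4 model.

    Defaults are a documented standard set from the C4 modelling
    literature; every field can be overridden via config.

    Attributes
    ----------
    Kc : Michaelis constant of Rubisco for CO2 (ubar).
    Ko : Michaelis constant of Rubisco for O2 (mbar).
    Kp : Michaelis constant for CO2 of PEP carboxylation (ubar).
    gamma_star : half the reciprocal of Rubisco specificity (bar/bar).
    Os : bundle-sheath O2 partial pressure (mbar).
    gbs : bundle-sheath conductance to CO2 (mol m-2 s-1 bar-1).
    x : partitioning factor of electron transport to the C4 cycle.
    phi : ATP requirement of the C4 cycle.
    rm_ratio : ratio of mesophyll respiration Rm to leaf respiration Rd.
    """

    Kc: float = 1210.0
    Ko: float = 292.0
    Kp: float = 82.0
    gamma_star: float = 0.000193
    Os: float = 210.0
    gbs: float = 0.003
    x: float = 0.4
    phi: float = 2.0
    rm_ratio: float = 0.5

    def __post_init__(self) -> None:
        for name in ("Kc", "Ko", "Kp", "gamma_star", "Os", "gbs", "phi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"C4Constants.{name} must be strictly positive")
        if not 0 < self.x < 1:
            raise ValueError("C4Constants.x must lie in (0, 1)")
        if not 0 < self.rm_ratio <= 1:
            raise ValueError("C4Constants.rm_ratio must lie in (0, 1]")

    @property
    def gamma_star_Os(self) -> float:
        """gamma* x Os expressed in ubar (Os is stored in mbar)."""
        return self.gamma_star * self.Os * 1000.0

    @property
    def Kc_eff(self) -> float:
        """Effective Michaelis term Kc (1 + Os/Ko) in ubar."""
        return self.Kc * (1.0 + self.Os / self.Ko)


@dataclass(frozen=True)
class LeafPhotoParams:
    """Leaf-level photosynthetic parameter set.

    Vcmax, Vpmax, Jmax, Rd in umol m-2 s-1; theta dimensionless curvature
    of the light response; PSabs the fraction of incident light absorbed
    and useful to PSII; gm mesophyll conductance (mol m-2 s-1 bar-1).
    """

    Vcmax: float
    Vpmax: float
    Jmax: float
    Rd: float
    theta: float = 0.3
    PSabs: float = 0.35
    gm: float = 1.0

    def __post_init__(self) -> None:
        for name in ("Vcmax", "Vpmax", "Jmax", "Rd", "gm"):
            if getattr(self, name) < 0:
                raise ValueError(f"LeafPhotoParams.{name} must be non-negative")
        if not 0 < self.theta < 1:
            raise ValueError("LeafPhotoParams.theta must lie in (0, 1)")
        if not 0 < self.PSabs < 1:
            raise ValueError("LeafPhotoParams.PSabs must lie in (0, 1)")

    def replace(self, **kwargs) -> "LeafPhotoParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class LeafEnvironment:
    """Gas-exchange environment of a single measurement step.

    Either a measured intercellular CO2 (Ci, ubar) or a fixed Ci/Ca ratio
    may be supplied; Ci takes precedence when both are present.
    """

    Ca: float
    I_inc: float
    Ci: float | None = None
    Ci_over_Ca: float | None = None

    def __post_init__(self) -> None:
        if self.Ca < 0:
            raise ValueError("Ca must be non-negative")
        if self.I_inc < 0:
            raise ValueError("I_inc must be non-negative")
        if self.Ci is None and self.Ci_over_Ca is None:
            raise ValueError("provide either Ci or Ci_over_Ca")
        if self.Ci_over_Ca is not None and not 0 < self.Ci_over_Ca <= 1:
            raise ValueError("Ci_over_Ca must lie in (0, 1]")

    @property
    def ci(self) -> float:
        """Intercellular CO2 partial pressure (ubar)."""
        if self.Ci is not None:
            return self.Ci
        return self.Ca * self.Ci_over_Ca


def electron_transport_rate(I2: float, Jmax: float, theta: float) -> float:
    """Whole-chain electron transport rate Jt (umol m-2 s-1).

    Smaller root of the non-rectangular hyperbola
    ``theta Jt^2 - (I2 + Jmax) Jt + I2 Jmax = 0`` where I2 is the
    photosynthetically useful light absorbed by PSII.
    """
    if I2 < 0:
        raise ValueError("I2 must be non-negative")
    if Jmax <= 0:
        raise ValueError("Jmax must be strictly positive")
    if not 0 < theta < 1:
        raise ValueError("theta must lie in (0, 1)")
    s = I2 + Jmax
    disc = s * s - 4.0 * theta * I2 * Jmax
    if disc < 0:
        raise ArithmeticError("negative discriminant in electron transport quadratic")
    # stable form: larger root first, smaller root via the product identity
    # (avoids cancellation in s - sqrt(disc)); one Newton step polishes the
    # residual down to rounding level
    big = (s + np.sqrt(disc)) / (2.0 * theta)
    jt = (I2 * Jmax / theta) / big if big > 0 else 0.0
    dfdx = 2.0 * theta * jt - s
    if dfdx != 0.0:
        jt -= (theta * jt * jt - s * jt + I2 * Jmax) / dfdx
    return jt


def _enzyme_demand(A: float, ci: float, p: LeafPhotoParams, c: C4Constants) -> float:
    """Rubisco-limited rate Ac implied by assimilation flux A."""
    Cm = max(ci - A / p.gm, 0.0)
    Vp = Cm * p.Vpmax / (Cm + c.Kp)
    Rm = c.rm_ratio * p.Rd
    Cs = max(Cm + (Vp - A - Rm) / c.gbs, 0.0)
    return (Cs - c.gamma_star_Os) * p.Vcmax / (Cs + c.Kc_eff) - p.Rd


def _light_demand(A: float, ci: float, Jt: float, p: LeafPhotoParams,
                  c: C4Constants) -> float:
    """Electron-transport-limited rate Aj implied by assimilation flux A."""
    Cm = max(ci - A / p.gm, 0.0)
    Rm = c.rm_ratio * p.Rd
    Cs = max(Cm + (c.x * Jt / c.phi - A - Rm) / c.gbs, 1e-9)
    gs = c.gamma_star_Os
    gross = (1.0 - gs / Cs) * ((1.0 - c.x) * Jt / 3.0) / (1.0 + 7.0 * gs / (3.0 * Cs))
    return gross - p.Rd


def _solve_fixed_point(demand, lo: float, hi: float) -> float:
    """Smallest root of f(A) = A - demand(A) on [lo, hi].

    demand(A) is non-increasing in A for this model (raising the flux
    lowers Cm and Cs, hence the achievable rate), so f is increasing and
    the root is unique; a coarse scan backs up the rare non-bracketing
    case and picks the smallest root if several sign changes exist.
    """
    f = lambda A: A - demand(A)
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if flo < 0.0 < fhi:
        return brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16)
    grid = np.linspace(lo, hi, 257)
    vals = np.array([f(a) for a in grid])
    sign = np.sign(vals)
    idx = np.flatnonzero(np.diff(sign) != 0)
    if idx.size == 0:
        raise ConvergenceError(
            f"no self-consistent assimilation rate in [{lo:.3g}, {hi:.3g}]; "
            f"f(lo)={flo:.3g}, f(hi)={fhi:.3g}"
        )
    i = idx[0]  # smallest root: the "supply limits demand" branch
    return brentq(f, grid[i], grid[i + 1], xtol=1e-12, rtol=8.9e-16)


def _check_physical(A: float, env: LeafEnvironment, p: LeafPhotoParams) -> None:
    if env.ci - A / p.gm <= 0.0 and A > 0.0:
        warnings.warn(
            f"mesophyll CO2 non-positive at solution (A={A:.3g}, Ci={env.ci:.3g})",
            NonPhysicalWarning,
            stacklevel=3,
        )


def enzyme_limited_A(env: LeafEnvironment, params: LeafPhotoParams,
                     consts: C4Constants = C4Constants()) -> float:
    """Enzyme-limited net assimilation (umol m-2 s-1).

    Solves the coupled system Cm = Ci - A/gm, Vp = Cm Vpmax/(Cm + Kp),
    Cs = Cm + (Vp - A - Rm)/gbs, A = Ac(Cs) self-consistently in A.
    """
    ci = env.ci
    lo = -params.Rd - 1.0
    hi = min(params.Vcmax, params.Vpmax) + 1.0
    A = _solve_fixed_point(lambda a: _enzyme_demand(a, ci, params, consts), lo, hi)
    _check_physical(A, env, params)
    return A


def light_limited_A(env: LeafEnvironment, params: LeafPhotoParams,
                    consts: C4Constants = C4Constants()) -> float:
    """Electron-transport-limited net assimilation (umol m-2 s-1).

    I2 = PSabs x I_inc feeds the non-rectangular hyperbola for Jt; the
    C4 cycle receives x Jt/phi and the C3 cycle (1-x) Jt/3.
    """
    I2 = params.PSabs * env.I_inc
    if I2 == 0.0:
        return -params.Rd
    Jt = electron_transport_rate(I2, params.Jmax, params.theta)
    ci = env.ci
    lo = -params.Rd - 1.0
    hi = (1.0 - consts.x) * Jt / 3.0 + 1.0
    A = _solve_fixed_point(
        lambda a: _light_demand(a, ci, Jt, params, consts), lo, hi
    )
    _check_physical(A, env, params)
    return A


class Assimilation(NamedTuple):
    A: float
    regime: Literal["enzyme", "light"]
    Ac: float
    Aj: float


def net_assimilation(env: LeafEnvironment, params: LeafPhotoParams,
                     consts: C4Constants = C4Constants()) -> Assimilation:
    """Net assimilation A = min(Ac, Aj) and the limiting regime."""
    Ac = enzyme_limited_A(env, params, consts)
    Aj = light_limited_A(env, params, consts)
    if Ac <= Aj:
        return Assimilation(Ac, "enzyme", Ac, Aj)
    return Assimilation(Aj, "light", Ac, Aj)


def predict_curve(protocol, params: LeafPhotoParams,
                  consts: C4Constants = C4Constants()):
    """Forward-simulate a gas-exchange response curve.

    ``protocol`` is a :class:`~c4spectra.curves.CurveProtocol`; one net
    assimilation value is predicted per protocol step, in protocol order.
    Returns a :class:`~c4spectra.curves.ResponseCurve` whose ``A_obs``
    column holds the noise-free model prediction.
    """
    from .curves import CurveStep, ResponseCurve

    if len(protocol.steps) == 0:
        raise ValueError("empty protocol")
    steps = []
    for ca, i_inc in protocol.steps:
        env = LeafEnvironment(Ca=ca, I_inc=i_inc, Ci_over_Ca=protocol.ci_over_ca)
        a = net_assimilation(env, params, consts).A
        steps.append(CurveStep(A_obs=a, Ca=ca, Ci=env.ci, I_inc=i_inc))
    return ResponseCurve(kind=protocol.kind, steps=steps)
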