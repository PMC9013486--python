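"""Estimation of leaf photosynthetic parameters from response curves.

The inversion is two-stage, mirroring field practice: the light-response
(Ai) curve is fitted first for (Jmax, theta, PSabs, Rd) using the
electron-transport-limited branch only; those values are then held fixed
while the CO2-response (ACi) curve is fitted for (Vcmax, Vpmax) using the
full min(Ac, Aj) model.  Both stages minimise the sum of squared errors
in A with bounded nonlinear least squares and seeded multi-starts.

Post-fit screening drops extreme parameter values (Vcmax > 65,
Vpmax > 750, Jmax > 700 umol m-2 s-1, strict inequalities) as outliers,
per trait, so each trait keeps its own valid plot set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .c4_model import (
    C4Constants,
    ConvergenceError,
    LeafEnvironment,
    LeafPhotoParams,
    NonPhysicalWarning,
    enzyme_limited_A,
    light_limited_A,
)
from .curves import ResponseCurve

__all__ = [
    "FitConfig",
    "FitResult",
    "NonIdentifiableError",
    "OUTLIER_THRESHOLDS",
    "fit_ai",
    "fit_aci",
    "fit_two_stage",
    "flag_outliers",
    "outlier_mask",
    "fits_to_frame",
]

#: Strict upper thresholds beyond which a fitted value is excluded (per trait).
OUTLIER_THRESHOLDS: dict[str, float] = {"Vcmax": 65.0, "Vpmax": 750.0, "Jmax": 700.0}


class NonIdentifiableError(ValueError):
    """The curve carries no usable signal (e.g. flat A across steps)."""


@dataclass(frozen=True)
class FitConfig:
    """Optimiser settings for the two-stage fit.

    Bounds are boxes per parameter; ``n_starts`` seeded multi-starts are
    drawn log-uniformly within bounds (the first start is a heuristic
    initial guess).  ``fix_theta`` pins the light-response curvature
    instead of fitting it.  ``gm`` is held fixed, not fitted.
    """

    bounds_Jmax: tuple[float, float] = (50.0, 1000.0)
    bounds_theta: tuple[float, float] = (0.05, 0.95)
    bounds_PSabs: tuple[float, float] = (0.05, 0.9)
    bounds_Rd: tuple[float, float] = (1e-3, 10.0)
    bounds_Vcmax: tuple[float, float] = (5.0, 150.0)
    bounds_Vpmax: tuple[float, float] = (20.0, 1200.0)
    n_starts: int = 5
    seed: int = 0
    fix_theta: float | None = None
    gm: float = 1.0
    ci_over_ca: float = 0.4
    ftol: float = 1e-10
    xtol: float = 1e-10


@dataclass
class FitResult:
    """Fitted parameter set for one curve, with fit diagnostics."""

    params: LeafPhotoParams
    sse: float
    n_points: int
    converged: bool
    source_stage: Literal["ai", "aci"]
    plot_id: str = ""
    genotype: str = ""
    outlier: bool = False
    outlier_traits: tuple[str, ...] = ()
    #: False when the enzyme-limited branch never binds across the CO2 steps,
    #: in which case the ACi curve carries no information on Vcmax (the curve
    #: is transport-capped) and the fitted Vcmax is not usable downstream.
    vcmax_identifiable: bool = True


def _envs_for_curve(curve: ResponseCurve, config: FitConfig) -> list[LeafEnvironment]:
    """Per-step environments; measured Ci is preferred when present."""
    envs = []
    for s in curve.steps:
        if s.Ci is not None and np.isfinite(s.Ci):
            envs.append(LeafEnvironment(Ca=s.Ca, I_inc=s.I_inc, Ci=s.Ci))
        else:
            envs.append(
                LeafEnvironment(Ca=s.Ca, I_inc=s.I_inc, Ci_over_Ca=config.ci_over_ca)
            )
    return envs


def _predict_light(envs, params, consts) -> np.ndarray:
    out = np.empty(len(envs))
    with warnings.catch_warnings():
        # non-physical excursions on the unused branch are routine mid-search
        warnings.simplefilter("ignore", NonPhysicalWarning)
        for i, env in enumerate(envs):
            try:
                out[i] = light_limited_A(env, params, consts)
            except ConvergenceError:
                out[i] = 1e3  # push the optimiser away from pathological regions
    return out


def _multistart(residual, x0: np.ndarray, lo: np.ndarray, hi: np.ndarray,
                config: FitConfig):
    """Bounded least squares from seeded starts; best SSE wins.

    Ties (within 1e-12 relative) break toward the smaller parameter-vector
    norm for determinism.
    """
    rng = np.random.default_rng(config.seed)
    starts = [x0]
    for _ in range(max(config.n_starts - 1, 0)):
        u = rng.uniform(size=x0.size)
        starts.append(np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo))))
    best = None
    for s in starts:
        s = np.clip(s, lo, hi)
        try:
            res = least_squares(
                residual, s, bounds=(lo, hi), method="trf",
                ftol=config.ftol, xtol=config.xtol,
            )
        except Exception:
            continue
        sse = float(np.sum(res.fun**2))
        if best is None:
            best = (sse, res)
            continue
        if sse < best[0] * (1 - 1e-12):
            best = (sse, res)
        elif abs(sse - best[0]) <= 1e-12 * max(best[0], 1.0):
            if np.linalg.norm(res.x) < np.linalg.norm(best[1].x):
                best = (sse, res)
    if best is None:
        raise ConvergenceError("all optimiser starts failed")
    return best


def fit_ai(curve: ResponseCurve, consts: C4Constants = C4Constants(),
           config: FitConfig = FitConfig()) -> FitResult:
    """Fit (Jmax, theta, PSabs, Rd) to a light-response curve.

    Rd is anchored by the dark step (I_inc = 0) when the protocol has one.
    Raises :class:`NonIdentifiableError` for a flat curve.
    """
    if curve.kind != "Ai":
        raise ValueError("fit_ai expects an Ai curve")
    curve.validate_for_fitting()
    a_obs = curve.A_obs
    if np.std(a_obs) < 1e-8:
        raise NonIdentifiableError("Ai curve is flat; parameters not identifiable")
    envs = _envs_for_curve(curve, config)

    fit_theta = config.fix_theta is None
    lo = [config.bounds_Jmax[0], config.bounds_PSabs[0], config.bounds_Rd[0]]
    hi = [config.bounds_Jmax[1], config.bounds_PSabs[1], config.bounds_Rd[1]]
    dark = curve.I_inc == 0
    rd0 = float(np.clip(-a_obs[dark].mean() if dark.any() else 2.0,
                        config.bounds_Rd[0] + 1e-6, config.bounds_Rd[1] - 1e-6))
    x0 = [400.0, 0.35, rd0]
    if fit_theta:
        lo.insert(1, config.bounds_theta[0])
        hi.insert(1, config.bounds_theta[1])
        x0.insert(1, 0.3)
    lo, hi, x0 = np.array(lo), np.array(hi), np.array(x0)

    def unpack(x):
        if fit_theta:
            jmax, theta, psabs, rd = x
        else:
            jmax, psabs, rd = x
            theta = config.fix_theta
        return LeafPhotoParams(Vcmax=1.0, Vpmax=1.0, Jmax=jmax, Rd=rd,
                               theta=theta, PSabs=psabs, gm=config.gm)

    def residual(x):
        return _predict_light(envs, unpack(x), consts) - a_obs

    sse, res = _multistart(residual, x0, lo, hi, config)
    p = unpack(res.x)
    return FitResult(
        params=p, sse=sse, n_points=len(curve), converged=bool(res.success),
        source_stage="ai", plot_id=curve.plot_id, genotype=curve.genotype,
    )


def fit_aci(curve: ResponseCurve, ai_fit: FitResult,
            consts: C4Constants = C4Constants(),
            config: FitConfig = FitConfig()) -> FitResult:
    """Fit (Vcmax, Vpmax) to a CO2-response curve.

    Jmax, theta, PSabs and Rd are taken from the Ai-stage fit and held
    fixed.  The light-limited rate per step does not depend on (Vcmax,
    Vpmax) and is precomputed once; the optimiser then solves only the
    enzyme-limited branch and applies min(Ac, Aj).
    """
    if curve.kind != "ACi":
        raise ValueError("fit_aci expects an ACi curve")
    curve.validate_for_fitting()
    a_obs = curve.A_obs
    if np.std(a_obs) < 1e-8:
        raise NonIdentifiableError("ACi curve is flat; parameters not identifiable")
    envs = _envs_for_curve(curve, config)
    ci = np.array([e.ci for e in envs])
    if np.sum(ci < 150.0) < 2:
        warnings.warn(
            "fewer than 2 steps below 150 ubar Ci: Vpmax weakly identified",
            UserWarning,
        )

    base = ai_fit.params
    aj = _predict_light(envs, base, consts)

    lo = np.array([config.bounds_Vcmax[0], config.bounds_Vpmax[0]])
    hi = np.array([config.bounds_Vcmax[1], config.bounds_Vpmax[1]])
    x0 = np.clip(np.array([50.0, 400.0]), lo, hi)

    def residual(x):
        p = base.replace(Vcmax=x[0], Vpmax=x[1])
        ac = np.empty(len(envs))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", NonPhysicalWarning)
            for i, env in enumerate(envs):
                try:
                    ac[i] = enzyme_limited_A(env, p, consts)
                except ConvergenceError:
                    ac[i] = 1e3
        return np.minimum(ac, aj) - a_obs

    sse, res = _multistart(residual, x0, lo, hi, config)
    p = base.replace(Vcmax=float(res.x[0]), Vpmax=float(res.x[1]))

    # identifiability diagnostic: Vcmax is informed only where the Rubisco-
    # saturated branch shapes min(Ac, Aj).  On a transport-capped curve (or
    # with the fit pinned at a Vcmax bound) perturbing Vcmax leaves the
    # predicted curve unchanged and the estimate cannot be trusted.
    dv = 0.05 * p.Vcmax
    sens = np.abs(residual(np.array([p.Vcmax + dv, p.Vpmax]))
                  - residual(np.array([p.Vcmax, p.Vpmax]))) / dv
    at_bound = (p.Vcmax >= config.bounds_Vcmax[1] - 1e-6
                or p.Vcmax <= config.bounds_Vcmax[0] + 1e-6)
    return FitResult(
        params=p, sse=sse, n_points=len(curve), converged=bool(res.success),
        source_stage="aci", plot_id=curve.plot_id, genotype=curve.genotype,
        # 0.4 resolves a 10% Vcmax change above the ~1 umol m-2 s-1
        # measurement noise of a saturating step
        vcmax_identifiable=bool(sens.max() >= 0.4 and not at_bound),
    )


def fit_two_stage(ai_curve: ResponseCurve, aci_curve: ResponseCurve,
                  consts: C4Constants = C4Constants(),
                  config: FitConfig = FitConfig()) -> FitResult:
    """Convenience wrapper: Ai stage then ACi stage for one plot."""
    ai = fit_ai(ai_curve, consts, config)
    return fit_aci(aci_curve, ai, consts, config)


def flag_outliers(fits: Iterable[FitResult]) -> list[FitResult]:
    """Apply the strict extreme-value exclusion rules.

    A fit is marked ``outlier`` if any trait exceeds its threshold; the
    per-trait breakdown is kept in ``outlier_traits`` so each trait can
    retain its own valid plot set downstream.
    """
    out = []
    for f in fits:
        traits = tuple(
            t for t, thr in OUTLIER_THRESHOLDS.items()
            if getattr(f.params, t) > thr
        )
        out.append(
            FitResult(
                params=f.params, sse=f.sse, n_points=f.n_points,
                converged=f.converged, source_stage=f.source_stage,
                plot_id=f.plot_id, genotype=f.genotype,
                outlier=bool(traits), outlier_traits=traits,
                vcmax_identifiable=f.vcmax_identifiable,
            )
        )
    return out


def outlier_mask(values: pd.Series | np.ndarray, trait: str) -> np.ndarray:
    """Boolean keep-mask for one trait column under the strict rules."""
    v = np.asarray(values, dtype=float)
    thr = OUTLIER_THRESHOLDS.get(trait)
    if thr is None:
        return np.ones(v.shape, dtype=bool)
    return ~(v > thr)


def fits_to_frame(fits: Iterable[FitResult]) -> pd.DataFrame:
    rows = []
    for f in fits:
        rows.append(
            {
                "plot_id": f.plot_id,
                "genotype": f.genotype,
                "stage": f.source_stage,
                "Vcmax": f.params.Vcmax,
                "Vpmax": f.params.Vpmax,
                "Jmax": f.params.Jmax,
                "Rd": f.params.Rd,
                "theta": f.params.theta,
                "PSabs": f.params.PSabs,
                "sse": f.sse,
                "n_points": f.n_points,
                "converged": f.converged,
                "vcmax_identifiable": f.vcmax_identifiable,
                "outlier": f.outlier,
                "outlier_traits": ";".join(f.outlier_traits),
            }
        )
    return pd.DataFrame(rows)
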