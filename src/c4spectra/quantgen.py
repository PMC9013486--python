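"""Genotype BLUPs and generalised heritability from field-trial layouts.

Plot-level trait values from a row-column trial are modelled by a linear
mixed model

    y = X beta + Z_g u_g [+ Z_r u_r + Z_c u_c] + e

with fixed intercept and linear row/column trends, a random genotype
effect, optional random row and column factors, and independent
residuals.  Variance components are estimated by REML (profiled over the
residual variance, optimised over log variance ratios), genotype BLUPs
follow from the mixed-model equations, and the average standard error of
a difference (SED) between genotype BLUPs comes from the prediction
error variance matrix.  Generalised heritability is

    H^2 = 1 - mean(SED)^2 / (2 sigma_g^2),

appropriate when shrinkage and unbalanced replication make the classical
line-mean formula inapplicable.

This is a deliberately simplified variance structure: no autoregressive
(AR1 x AR1) spatial residual correlation and single-trial analysis only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

__all__ = [
    "MixedModelConfig",
    "BlupResult",
    "HeritabilityResult",
    "fit_mixed_model",
    "heritability",
    "blup_pipeline",
]


@dataclass(frozen=True)
class MixedModelConfig:
    """Structure switches and numerical settings for the trial model."""

    random_row: bool = True
    random_col: bool = True
    fixed_row_trend: bool = True
    fixed_col_trend: bool = True
    max_pairs: int = 5000     # SED pairs sampled when n_genotypes > 200
    seed: int = 0
    # genotype variance ratio sigma_g^2/sigma_e^2 below which the genetic
    # variance is treated as at the zero boundary (genetically negligible)
    boundary_gamma: float = 0.02


@dataclass
class HeritabilityResult:
    value: float
    flagged: bool = False
    reason: str = ""


@dataclass
class BlupResult:
    """REML fit summary for one trait."""

    trait: str
    blups: pd.Series                 # genotype effects, trait units
    genotype_predictions: pd.Series  # intercept + BLUP
    sigma2_g: float
    sigma2_e: float
    sigma2_row: float
    sigma2_col: float
    sed_bar: float
    h2: float
    h2_flagged: bool
    loglik: float
    boundary: bool
    n_obs: int
    intercept: float


def _design(table: pd.DataFrame, trait: str, config: MixedModelConfig):
    y = table[trait].to_numpy(float)
    n = len(y)
    cols = [np.ones(n)]
    if config.fixed_row_trend:
        r = table["row"].to_numpy(float)
        cols.append((r - r.mean()) / max(r.std(), 1.0))
    if config.fixed_col_trend:
        c = table["col"].to_numpy(float)
        cols.append((c - c.mean()) / max(c.std(), 1.0))
    X = np.column_stack(cols)

    def dummies(s: pd.Series) -> tuple[np.ndarray, pd.Index]:
        cat = pd.Categorical(s)
        Z = np.zeros((n, len(cat.categories)))
        Z[np.arange(n), cat.codes] = 1.0
        return Z, cat.categories

    Zg, genos = dummies(table["genotype"])
    Zs = [Zg]
    if config.random_row:
        Zs.append(dummies(table["row"])[0])
    if config.random_col:
        Zs.append(dummies(table["col"])[0])
    return y, X, Zs, genos


def _reml_nll(log_gammas, y, X, Zs):
    """Negative REML log-likelihood profiled over sigma_e^2."""
    n, p = X.shape
    V1 = np.eye(n)
    for lg, Z in zip(log_gammas, Zs):
        V1 += np.exp(lg) * (Z @ Z.T)
    try:
        cf = cho_factor(V1, lower=True)
    except np.linalg.LinAlgError:
        return 1e10
    logdet_V1 = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Vi_y = cho_solve(cf, y)
    Vi_X = cho_solve(cf, X)
    XtViX = X.T @ Vi_X
    sign, logdet_XtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return 1e10
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    quad = float(r @ cho_solve(cf, r))
    if quad <= 0:
        return 1e10
    s2e = quad / (n - p)
    nll = 0.5 * (logdet_V1 + logdet_XtViX + (n - p) * (1.0 + np.log(2.0 * np.pi * s2e)))
    return nll


def heritability(sigma2_g: float, sed_bar: float) -> HeritabilityResult:
    """Generalised heritability H^2 = 1 - SEDbar^2 / (2 sigma_g^2).

    sigma_g^2 = 0 reports H^2 = 0 with a boundary flag; negative values
    of the formula are reported as-is (not clipped) and flagged.
    """
    if sigma2_g < 0 or sed_bar < 0:
        raise ValueError("sigma2_g and sed_bar must be non-negative")
    if sigma2_g == 0:
        return HeritabilityResult(0.0, flagged=True, reason="sigma2_g at boundary 0")
    h2 = 1.0 - sed_bar**2 / (2.0 * sigma2_g)
    if h2 < 0:
        return HeritabilityResult(h2, flagged=True, reason="negative H2")
    return HeritabilityResult(h2)


def fit_mixed_model(table: pd.DataFrame, trait: str,
                    config: MixedModelConfig = MixedModelConfig()) -> BlupResult:
    """REML fit of the row-column trial model for one trait.

    ``table`` needs columns plot_id, genotype, row, col and the trait.
    Returns variance components, genotype BLUPs, the mean SED over
    genotype pairs and the generalised heritability.
    """
    required = {"genotype", "row", "col", trait}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if table.duplicated(subset=["row", "col"]).any():
        raise ValueError("duplicate (row, col) positions in trial layout")
    table = table.dropna(subset=[trait])
    if table["genotype"].nunique() < 2:
        raise ValueError("need at least 2 genotypes")
    if not (table["genotype"].value_counts() > 1).any():
        warnings.warn("no replicated genotype: genetic variance weakly identified")

    y, X, Zs, genos = _design(table, trait, config)
    n, p = X.shape

    x0 = np.zeros(len(Zs))
    best = None
    for start in (x0, x0 - 2.0, x0 + 2.0):
        res = minimize(
            _reml_nll, start, args=(y, X, Zs), method="L-BFGS-B",
            bounds=[(-12.0, 8.0)] * len(Zs),
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("REML did not converge")
    gammas = np.exp(best.x)

    # recompute quantities at the optimum
    V1 = np.eye(n)
    for g, Z in zip(gammas, Zs):
        V1 += g * (Z @ Z.T)
    cf = cho_factor(V1, lower=True)
    Vi_y = cho_solve(cf, y)
    Vi_X = cho_solve(cf, X)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    Vi_r = cho_solve(cf, r)
    s2e = float(r @ Vi_r) / (n - p)

    gam_g = gammas[0]
    sigma2_g = gam_g * s2e
    sigma2_row = gammas[1] * s2e if config.random_row else 0.0
    i_col = 1 + int(config.random_row)
    sigma2_col = gammas[i_col] * s2e if config.random_col else 0.0
    boundary = gam_g <= config.boundary_gamma

    Zg = Zs[0]
    u = gam_g * (Zg.T @ Vi_r)

    # prediction error variance of genotype effects:
    # PEV = s2e (gamma_g I - gamma_g^2 M), M = Zg'P1 Zg
    Vi_Zg = cho_solve(cf, Zg)
    M = Zg.T @ Vi_Zg - (Zg.T @ Vi_X) @ np.linalg.solve(XtViX, Vi_X.T @ Zg)
    PEV = s2e * (gam_g * np.eye(len(genos)) - gam_g**2 * M)

    G = len(genos)
    if G > 200:
        rng = np.random.default_rng(config.seed)
        ii = rng.integers(0, G, size=config.max_pairs)
        jj = rng.integers(0, G - 1, size=config.max_pairs)
        jj = np.where(jj >= ii, jj + 1, jj)
    else:
        ii, jj = np.triu_indices(G, k=1)
    pev_diff = PEV[ii, ii] + PEV[jj, jj] - 2.0 * PEV[ii, jj]
    sed_bar = float(np.mean(np.sqrt(np.maximum(pev_diff, 0.0))))

    h2res = heritability(0.0 if boundary else sigma2_g, sed_bar)
    intercept = float(beta[0])
    blups = pd.Series(u, index=genos, name=trait)
    return BlupResult(
        trait=trait,
        blups=blups,
        genotype_predictions=blups + intercept,
        sigma2_g=sigma2_g,
        sigma2_e=s2e,
        sigma2_row=sigma2_row,
        sigma2_col=sigma2_col,
        sed_bar=sed_bar,
        h2=h2res.value,
        h2_flagged=h2res.flagged,
        loglik=-float(best.fun),
        boundary=boundary,
        n_obs=n,
        intercept=intercept,
    )


def blup_pipeline(predictions: pd.DataFrame, layout: pd.DataFrame,
                  traits: list[str] | None = None,
                  config: MixedModelConfig = MixedModelConfig()):
    """Per-trait BLUP + heritability over a predicted-trait table.

    ``predictions`` carries plot_id plus trait columns; ``layout`` carries
    plot_id, genotype, row, col.  Returns (results dict, summary frame
    with min/max/mean/std.error/H2 per trait, Table-4 style).
    """
    table = layout.merge(predictions, on="plot_id", how="inner")
    if traits is None:
        traits = [c for c in predictions.columns if c != "plot_id"]
    results: dict[str, BlupResult] = {}
    rows = []
    for trait in traits:
        if trait not in table.columns:
            warnings.warn(f"trait {trait!r} missing from predictions; skipped")
            continue
        res = fit_mixed_model(table, trait, config)
        results[trait] = res
        gp = res.genotype_predictions
        rows.append(
            {
                "trait": trait,
                "min": float(gp.min()),
                "max": float(gp.max()),
                "mean": float(gp.mean()),
                "std.error": res.sed_bar / np.sqrt(2.0),
                "H2": res.h2,
            }
        )
    summary = pd.DataFrame(rows, columns=["trait", "min", "max", "mean",
                                          "std.error", "H2"])
    return results, summary
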