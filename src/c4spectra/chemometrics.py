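"""Trait prediction from spectra: stepwise index regression and PLSR.

Two complementary approaches link canopy reflectance to leaf traits:

* Approach 1 — reduce the vegetation-index set with a PCA-guided
  decorrelation step, then bidirectional stepwise multilinear regression
  selected by AIC.
* Approach 2 — full-spectrum partial least squares regression (PLSR) on
  all 272 bands, with the number of latent variables chosen by
  leave-one-out cross-validation (one-standard-error rule on RMSEP,
  capped at 25 components).

The observational unit throughout is the plot.  Reported R^2 is by
default the squared Pearson correlation between (cross-validated)
predictions and observations; 1 - SSE/SST is available via
``r2_method="ss"``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA

__all__ = [
    "SubsetResult",
    "StepwiseModel",
    "PLSRModel",
    "pca_index_subset",
    "stepwise_aic",
    "fit_plsr",
    "loocv",
    "predict_traits",
    "r_squared",
]


def r_squared(obs: np.ndarray, pred: np.ndarray, method: str = "pearson") -> float:
    """R^2 between observations and predictions.

    ``pearson``: squared Pearson correlation (scatter-plot convention);
    ``ss``: 1 - SSE/SST.
    """
    obs = np.asarray(obs, float)
    pred = np.asarray(pred, float)
    if method == "pearson":
        if np.std(obs) == 0 or np.std(pred) == 0:
            return 0.0
        return float(np.corrcoef(obs, pred)[0, 1] ** 2)
    if method == "ss":
        sst = np.sum((obs - obs.mean()) ** 2)
        if sst == 0:
            return 0.0
        return float(1.0 - np.sum((obs - pred) ** 2) / sst)
    raise ValueError(f"unknown r2 method {method!r}")


# ---------------------------------------------------------------------------
# Approach 1: PCA-guided subsetting + stepwise AIC
# ---------------------------------------------------------------------------


@dataclass
class SubsetResult:
    """Decorrelated index subset with the PCA diagnostics used to pick it."""

    selected: list[str]
    pc_variance: tuple[float, float]  # % variance of PCs 1-2
    dropped_constant: list[str] = field(default_factory=list)


def pca_index_subset(index_table: pd.DataFrame, corr_threshold: float = 0.9,
                     override: Sequence[str] | None = None) -> SubsetResult:
    """Reduce a vegetation-index table to a low-collinearity subset.

    Indices are standardised and decomposed by PCA.  Pairs with
    |Pearson r| above ``corr_threshold`` are linked into clusters
    (connected components); within each cluster the member with the
    largest squared-loading sum on PCs 1-2 is kept (ties break
    lexicographically).  ``override`` short-circuits the automatic rule
    with an analyst-chosen list.
    """
    df = index_table.copy()
    dropped = [c for c in df.columns if np.std(df[c].to_numpy(float)) == 0
               or df[c].isna().any()]
    if dropped:
        warnings.warn(f"dropping constant/missing indices: {dropped}")
        df = df.drop(columns=dropped)
    if df.shape[0] < 3:
        raise ValueError("need at least 3 plots for PCA subsetting")

    X = df.to_numpy(float)
    Xs = (X - X.mean(axis=0)) / X.std(axis=0)
    n_comp = min(Xs.shape[0] - 1, Xs.shape[1], 2)
    pca = PCA(n_components=n_comp)
    pca.fit(Xs)
    # loadings scaled by singular values: component weight x sqrt(variance)
    load = pca.components_.T * np.sqrt(pca.explained_variance_)
    score = (load[:, : min(2, n_comp)] ** 2).sum(axis=1)
    pc_var = tuple(
        float(100 * v) for v in list(pca.explained_variance_ratio_[:2]) + [0.0, 0.0]
    )[:2]

    if override is not None:
        missing = set(override) - set(df.columns)
        if missing:
            raise ValueError(f"override names not in table: {sorted(missing)}")
        return SubsetResult(list(override), pc_var, dropped)

    corr = np.abs(np.corrcoef(Xs, rowvar=False))
    cols = list(df.columns)
    p = len(cols)
    # union-find over the |r| > threshold graph
    parent = list(range(p))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(p):
        for j in range(i + 1, p):
            if corr[i, j] > corr_threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    clusters: dict[int, list[int]] = {}
    for i in range(p):
        clusters.setdefault(find(i), []).append(i)

    selected = []
    for members in clusters.values():
        best = sorted(members, key=lambda i: (-score[i], cols[i]))[0]
        selected.append(cols[best])
    return SubsetResult(sorted(selected), pc_var, dropped)


@dataclass
class StepwiseModel:
    """OLS model found by bidirectional stepwise AIC search."""

    trait: str
    selected: list[str]
    coefficients: dict[str, float]
    intercept: float
    aic: float
    r2: float
    rmse: float
    p_value: float

    def predict(self, index_table: pd.DataFrame) -> np.ndarray:
        out = np.full(len(index_table), self.intercept)
        for name, b in self.coefficients.items():
            out = out + b * index_table[name].to_numpy(float)
        return out


def _ols_fit(X: pd.DataFrame, y: np.ndarray, cols: list[str]):
    design = sm.add_constant(X[cols].to_numpy(float)) if cols else \
        np.ones((len(y), 1))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        return None
    return sm.OLS(y, design).fit()


def stepwise_aic(X: pd.DataFrame, y: np.ndarray, trait: str = "") -> StepwiseModel:
    """Bidirectional stepwise OLS starting from the intercept-only model.

    At each step the single addition or removal giving the largest AIC
    decrease is applied; the search stops when no move decreases AIC.
    Rank-deficient candidate designs are skipped.  Deterministic given
    input column order (candidate ties break by column name).
    """
    y = np.asarray(y, float)
    if len(X) <= X.shape[1] + 2:
        warnings.warn("few observations relative to candidate indices")
    current: list[str] = []
    res = _ols_fit(X, y, current)
    aic = res.aic
    while True:
        moves = []
        for c in sorted(set(X.columns) - set(current)):
            r = _ols_fit(X, y, sorted(current + [c]))
            if r is not None:
                moves.append((r.aic, "add", c, r))
        for c in sorted(current):
            r = _ols_fit(X, y, sorted(set(current) - {c}))
            if r is not None:
                moves.append((r.aic, "drop", c, r))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[2]))
        best_aic, action, col, best_res = moves[0]
        if best_aic >= aic - 1e-10:
            break
        aic, res = best_aic, best_res
        if action == "add":
            current = sorted(current + [col])
        else:
            current = sorted(set(current) - {col})

    pred = res.predict()
    rmse = float(np.sqrt(np.mean((y - pred) ** 2)))
    if current:
        coefs = dict(zip(current, np.asarray(res.params)[1:]))
        intercept = float(np.asarray(res.params)[0])
        r2 = float(res.rsquared)
        p_value = float(res.f_pvalue)
    else:
        coefs, intercept, r2, p_value = {}, float(np.mean(y)), 0.0, float("nan")
    return StepwiseModel(
        trait=trait, selected=current, coefficients=coefs, intercept=intercept,
        aic=float(res.aic), r2=r2, rmse=rmse, p_value=p_value,
    )


# ---------------------------------------------------------------------------
# Approach 2: full-spectrum PLSR with LOOCV
# ---------------------------------------------------------------------------


def _nested_coefs(pls: PLSRegression, kmax: int) -> np.ndarray:
    """Regression coefficient vectors for 1..kmax components of one fit.

    PLS components are nested: with weights W, x-loadings P and
    y-loadings q from a kmax-component fit, the k-component coefficient
    vector is W_k (P_k' W_k)^-1 q_k.  Returns array (kmax, p) on the
    centred (and, if enabled, scaled) data scale.
    """
    W = pls.x_weights_
    P = pls.x_loadings_
    q = pls.y_loadings_.ravel()
    coefs = np.empty((kmax, W.shape[0]))
    for k in range(1, kmax + 1):
        Wk, Pk, qk = W[:, :k], P[:, :k], q[:k]
        # lstsq: components beyond the effective rank of X are degenerate
        sol, *_ = np.linalg.lstsq(Pk.T @ Wk, qk, rcond=None)
        coefs[k - 1] = Wk @ sol
    return coefs


@dataclass
class PLSRModel:
    """Fitted full-spectrum PLSR model for one trait.

    Prediction is affine in the input spectrum:
    ``y = (x - x_mean) / x_scale @ coef + y_mean``.
    """

    trait: str
    wavelengths: np.ndarray
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    coef: np.ndarray
    n_latent: int
    cv_r2: float
    cv_rmse: float
    cv_rmse_pct: float
    cv_predictions: np.ndarray
    rmsep_by_k: np.ndarray
    loadings_pc12: np.ndarray      # (p, 2) x-loadings of components 1-2
    pc12_x_variance: tuple[float, float]  # % X-variance explained
    insample_r2: float = float("nan")
    insample_rmse: float = float("nan")

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, float))
        if X_new.shape[1] != self.x_mean.size:
            raise ValueError(
                f"expected {self.x_mean.size} bands, got {X_new.shape[1]}"
            )
        return (X_new - self.x_mean) / self.x_scale @ self.coef + self.y_mean

    def to_json(self) -> str:
        d = {
            "trait": self.trait,
            "wavelengths": self.wavelengths.tolist(),
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_mean": self.y_mean,
            "coef": self.coef.tolist(),
            "n_latent": self.n_latent,
            "cv_r2": self.cv_r2,
            "cv_rmse": self.cv_rmse,
            "cv_rmse_pct": self.cv_rmse_pct,
            "pc12_x_variance": list(self.pc12_x_variance),
            "insample_r2": self.insample_r2,
            "insample_rmse": self.insample_rmse,
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "PLSRModel":
        d = json.loads(s)
        return cls(
            trait=d["trait"],
            wavelengths=np.array(d["wavelengths"]),
            x_mean=np.array(d["x_mean"]),
            x_scale=np.array(d["x_scale"]),
            y_mean=d["y_mean"],
            coef=np.array(d["coef"]),
            n_latent=d["n_latent"],
            cv_r2=d["cv_r2"],
            cv_rmse=d["cv_rmse"],
            cv_rmse_pct=d["cv_rmse_pct"],
            cv_predictions=np.array([]),
            rmsep_by_k=np.array([]),
            loadings_pc12=np.empty((0, 2)),
            pc12_x_variance=tuple(d["pc12_x_variance"]),
            insample_r2=d.get("insample_r2", float("nan")),
            insample_rmse=d.get("insample_rmse", float("nan")),
        )


def fit_plsr(X: np.ndarray, y: np.ndarray, max_latent: int = 25,
             trait: str = "", wavelengths: np.ndarray | None = None,
             scale: bool = False, r2_method: str = "pearson",
             n_latent: int | None = None) -> PLSRModel:
    """Fit PLSR with LOOCV-selected latent-variable count.

    For each left-out plot a single ``max_latent``-component PLS fit
    provides nested predictions for every component count; the chosen
    count is the smallest whose LOOCV RMSEP is within one standard error
    of the global minimum (``n_latent`` forces a count instead).
    Mean-centring only by default.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    if n < 10:
        raise ValueError("need at least 10 plots to train PLSR")
    if np.std(y) == 0:
        raise ValueError("constant response: PLSR not identifiable")
    if wavelengths is None:
        wavelengths = np.arange(p, dtype=float)
    kmax = int(min(max_latent, n - 2, p))
    if n_latent is not None:
        kmax = max(kmax, int(n_latent))

    def _prep(Xt):
        mu = Xt.mean(axis=0)
        sc = Xt.std(axis=0, ddof=1) if scale else np.ones(Xt.shape[1])
        sc = np.where(sc == 0, 1.0, sc)
        return mu, sc

    cv_pred = np.empty((n, kmax))
    for i in range(n):
        idx = np.arange(n) != i
        mu, sc = _prep(X[idx])
        pls = PLSRegression(n_components=kmax, scale=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pls.fit((X[idx] - mu) / sc, y[idx])
        coefs = _nested_coefs(pls, kmax)
        xc = (X[i] - mu) / sc
        cv_pred[i] = xc @ coefs.T + y[idx].mean()

    sq_err = (cv_pred - y[:, None]) ** 2
    rmsep = np.sqrt(sq_err.mean(axis=0))
    k_best = int(np.argmin(rmsep))
    # one-SE rule on the PAIRED per-observation squared-error difference:
    # the smallest k whose excess MSEP over the minimum is within one
    # standard error of that (paired) difference.  Pairing matters: errors
    # are strongly correlated across component counts, so the marginal SE
    # would grossly overstate the uncertainty of the comparison.
    if n_latent is None:
        n_latent = k_best + 1
        for k in range(k_best):
            d = sq_err[:, k] - sq_err[:, k_best]
            se_d = d.std(ddof=1) / np.sqrt(n)
            if d.mean() <= se_d:
                n_latent = k + 1
                break
    else:
        n_latent = int(min(n_latent, kmax))

    x_mean, x_scale = _prep(X)
    final = PLSRegression(n_components=n_latent, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit((X - x_mean) / x_scale, y)
    coef = _nested_coefs(final, n_latent)[n_latent - 1]

    # % X-variance explained by components 1-2 (orthogonal scores)
    Xc = (X - x_mean) / x_scale
    total_ss = np.sum(Xc**2)
    n_l2 = min(2, n_latent)
    comp_ss = [
        np.sum(final.x_scores_[:, k] ** 2) * np.sum(final.x_loadings_[:, k] ** 2)
        for k in range(n_l2)
    ]
    pc12 = tuple((100.0 * np.array(comp_ss + [0.0, 0.0])[:2] / total_ss).tolist())
    load12 = np.zeros((p, 2))
    load12[:, :n_l2] = final.x_loadings_[:, :n_l2]

    sel_pred = cv_pred[:, n_latent - 1]
    cv_rmse = float(np.sqrt(np.mean((sel_pred - y) ** 2)))
    fitted = Xc @ coef + y.mean()
    model = PLSRModel(
        trait=trait,
        wavelengths=np.asarray(wavelengths, float),
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=float(y.mean()),
        coef=coef,
        n_latent=n_latent,
        cv_r2=r_squared(y, sel_pred, r2_method),
        cv_rmse=cv_rmse,
        cv_rmse_pct=float(100.0 * cv_rmse / np.mean(y)) if np.mean(y) != 0 else float("nan"),
        cv_predictions=sel_pred,
        rmsep_by_k=rmsep,
        loadings_pc12=load12,
        pc12_x_variance=pc12,
        insample_r2=r_squared(y, fitted, r2_method),
        insample_rmse=float(np.sqrt(np.mean((fitted - y) ** 2))),
    )
    return model


def loocv(estimator_factory: Callable[[], object], X: np.ndarray,
          y: np.ndarray, r2_method: str = "pearson"):
    """Generic leave-one-out cross-validation over plots.

    ``estimator_factory`` returns a fresh object with sklearn-style
    ``fit(X, y)`` / ``predict(X)``.  Returns (predictions, r2, rmse,
    rmse_pct); a fold whose fit fails is recorded as NaN and flagged by
    the returned r2/rmse being computed over complete folds only.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 observations for LOOCV")
    pred = np.full(n, np.nan)
    for i in range(n):
        idx = np.arange(n) != i
        est = estimator_factory()
        try:
            est.fit(X[idx], y[idx])
            pred[i] = np.ravel(est.predict(X[i : i + 1]))[0]
        except Exception as exc:  # fold recorded missing
            warnings.warn(f"LOOCV fold {i} failed: {exc}")
    ok = np.isfinite(pred)
    if not ok.all():
        warnings.warn(f"LOOCV incomplete: {int((~ok).sum())} folds missing")
    r2 = r_squared(y[ok], pred[ok], r2_method)
    rmse = float(np.sqrt(np.mean((pred[ok] - y[ok]) ** 2)))
    rmse_pct = float(100.0 * rmse / np.mean(y[ok])) if np.mean(y[ok]) != 0 else float("nan")
    return pred, r2, rmse, rmse_pct


def predict_traits(model: PLSRModel, X_new: np.ndarray) -> np.ndarray:
    """Apply a trained PLSR model to new plot spectra (no re-fitting)."""
    return model.predict(X_new)
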