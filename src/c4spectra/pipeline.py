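"""End-to-end orchestration: simulate -> train -> extrapolate -> heritability.

`run_training` reproduces the training-set workflow: two-stage curve
fitting with extreme-value exclusion gives ground-truth photosynthetic
parameters per plot; SLN and LMA come from leaf sampling (here, the
generator); NDVI-masked plot spectra feed both the index/stepwise models
(Approach 1) and the full-spectrum PLSR models (Approach 2), scored by
leave-one-out cross-validation with the plot as observational unit.

`run_extrapolation` applies the trained PLSR models to an unseen trial's
plot spectra and summarises genotype BLUPs and generalised heritability
per trait.

`demo` wires both over the synthetic generator and scores predictions
against the generator's truth.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .c4_model import C4Constants
from .chemometrics import (
    PLSRModel,
    StepwiseModel,
    fit_plsr,
    pca_index_subset,
    r_squared,
    stepwise_aic,
)
from .curve_fitting import (
    FitConfig,
    NonIdentifiableError,
    fit_aci,
    fit_ai,
    fits_to_frame,
    flag_outliers,
    outlier_mask,
)
from .quantgen import MixedModelConfig, blup_pipeline
from .spectra import index_table, mask_and_average
from .synthetic_data import TRAITS, GeneratorConfig, simulate_trial

__all__ = ["RunConfig", "run_training", "run_extrapolation", "demo"]

PHOTO_TRAITS = ["Vcmax", "Vpmax", "Jmax"]
LEAF_TRAITS = ["SLN", "LMA"]


class RunConfig(BaseModel):
    """Configuration of one full pipeline run."""

    seed: int
    n_train_plots: int = 150
    n_train_genotypes: int = 120
    n_target_plots: int = 600
    n_target_genotypes: int = 450
    mask_threshold: float = 0.5
    max_latent: int = 25
    corr_threshold: float = 0.9
    r2_method: str = "pearson"
    scale_plsr: bool = False
    n_fit_starts: int = 5
    # theta "assumed as 0.3" in the protocol; the curve-fitting module can
    # also fit it freely (fix_theta=None)
    fix_theta: float | None = 0.3
    c4_constants: dict = Field(default_factory=dict)

    def consts(self) -> C4Constants:
        return C4Constants(**self.c4_constants)

    def manifest(self) -> dict:
        blob = self.model_dump_json().encode()
        return {
            "config_hash": hashlib.sha256(blob).hexdigest()[:16],
            "seed": self.seed,
            "version": __version__,
        }


def _mask_cubes(trial, threshold: float):
    """Plot reflectance matrix + retention counts for a simulated trial."""
    rows, ids, counts = [], [], []
    wavelengths = None
    for cube in trial.iter_cubes():
        pr = mask_and_average(cube, threshold=threshold)
        if pr.empty:
            warnings.warn(f"plot {cube.plot_id}: all pixels masked out")
            continue
        rows.append(pr.reflectance)
        ids.append(pr.plot_id)
        counts.append((pr.plot_id, pr.n_plant_pixels, pr.n_total_pixels))
        wavelengths = pr.wavelengths
    X = pd.DataFrame(np.vstack(rows), index=pd.Index(ids, name="plot_id"))
    counts = pd.DataFrame(counts, columns=["plot_id", "n_plant", "n_total"])
    return X, wavelengths, counts


def _fit_training_curves(trial, consts, fit_config):
    """Two-stage fits for every training plot; drops failures, flags outliers."""
    curves = trial.curves()
    by_plot: dict[str, dict] = {}
    for c in curves:
        by_plot.setdefault(c.plot_id, {})[c.kind] = c
    fits = []
    n_failed = 0
    for plot_id, d in by_plot.items():
        try:
            ai = fit_ai(d["Ai"], consts, fit_config)
            aci = fit_aci(d["ACi"], ai, consts, fit_config)
        except (NonIdentifiableError, RuntimeError):
            n_failed += 1
            continue
        if not aci.converged:
            n_failed += 1
            continue
        fits.append(aci)
    return flag_outliers(fits), n_failed


def run_training(config: RunConfig, trial=None) -> dict:
    """Train Approach 1 and Approach 2 models per trait on one trial.

    Returns a report dict with per-trait CV statistics, the trained
    models, attrition counts and the run manifest.
    """
    gen = GeneratorConfig(
        seed=config.seed,
        n_genotypes=config.n_train_genotypes,
        n_plots=config.n_train_plots,
    )
    if trial is None:
        trial = simulate_trial(gen)
    consts = config.consts()
    fit_config = FitConfig(
        seed=config.seed, n_starts=config.n_fit_starts, fix_theta=config.fix_theta
    )

    fits, n_failed = _fit_training_curves(trial, consts, fit_config)
    fit_df = fits_to_frame(fits).set_index("plot_id")

    X, wavelengths, counts = _mask_cubes(trial, config.mask_threshold)
    idx_tab = index_table_for(X, trial, config)

    # per-trait training labels: photosynthetic traits from curve fits
    # (per-trait outlier exclusion), leaf traits from destructive sampling
    labels: dict[str, pd.Series] = {}
    for t in PHOTO_TRAITS:
        keep = outlier_mask(fit_df[t], t)
        if t == "Vcmax":
            keep &= fit_df["vcmax_identifiable"].to_numpy(bool)
        labels[t] = fit_df.loc[keep, t]
    sampled = trial.plot_traits.set_index("plot_id")
    for t in LEAF_TRAITS:
        labels[t] = sampled[t]

    subset = pca_index_subset(idx_tab, corr_threshold=config.corr_threshold)
    models_plsr: dict[str, PLSRModel] = {}
    models_step: dict[str, StepwiseModel] = {}
    rows = []
    for trait, y in labels.items():
        common = y.index.intersection(X.index)
        if len(common) < 10:
            warnings.warn(f"trait {trait}: fewer than 10 usable plots, skipped")
            continue
        yv = y.loc[common].to_numpy(float)
        plsr = fit_plsr(
            X.loc[common].to_numpy(float), yv, max_latent=config.max_latent,
            trait=trait, wavelengths=wavelengths, scale=config.scale_plsr,
            r2_method=config.r2_method,
        )
        step = stepwise_aic(idx_tab.loc[common, subset.selected], yv, trait=trait)
        models_plsr[trait] = plsr
        models_step[trait] = step
        rows.append(
            {
                "trait": trait,
                "n_plots": len(common),
                "plsr_n_latent": plsr.n_latent,
                "plsr_cv_r2": plsr.cv_r2,
                "plsr_cv_rmse": plsr.cv_rmse,
                "plsr_cv_rmse_pct": plsr.cv_rmse_pct,
                "plsr_insample_r2": plsr.insample_r2,
                "plsr_insample_rmse": plsr.insample_rmse,
                "stepwise_indices": ";".join(step.selected),
                "stepwise_r2": step.r2,
                "stepwise_rmse": step.rmse,
                "stepwise_aic": step.aic,
            }
        )

    return {
        "trial": trial,
        "fit_table": fit_df,
        "n_curves_failed": n_failed,
        "n_outliers": int(fit_df["outlier"].sum()),
        "mask_counts": counts,
        "index_subset": subset.selected,
        "pc12_variance": subset.pc_variance,
        "models_plsr": models_plsr,
        "models_stepwise": models_step,
        "summary": pd.DataFrame(rows),
        "manifest": config.manifest(),
    }


def index_table_for(X: pd.DataFrame, trial, config: RunConfig) -> pd.DataFrame:
    """Vegetation-index table recomputed from the masked plot spectra."""
    from .spectra import PlotReflectance, compute_indices, default_wavelengths

    w = default_wavelengths()
    rows = {}
    for pid, r in zip(X.index, X.to_numpy(float)):
        pr = PlotReflectance(
            wavelengths=w, reflectance=r, n_plant_pixels=1, n_total_pixels=1,
            plot_id=pid,
        )
        rows[pid] = compute_indices(pr)
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("plot_id")


def run_extrapolation(config: RunConfig, models_plsr: dict[str, PLSRModel],
                      trial=None) -> dict:
    """Predict traits for an unseen trial, then BLUPs and heritability."""
    gen = GeneratorConfig(
        seed=config.seed + 500,
        n_genotypes=config.n_target_genotypes,
        n_plots=config.n_target_plots,
    )
    if trial is None:
        trial = simulate_trial(gen)
    X, _, counts = _mask_cubes(trial, config.mask_threshold)

    pred = pd.DataFrame(index=X.index)
    for trait, model in models_plsr.items():
        pred[trait] = model.predict(X.to_numpy(float))
    pred = pred.reset_index()

    mm = MixedModelConfig(seed=config.seed)
    results, table4 = blup_pipeline(pred, trial.layout, list(models_plsr), mm)

    truth = trial.plot_traits.set_index("plot_id")
    r2_vs_truth = {
        t: r_squared(
            truth.loc[pred["plot_id"], t].to_numpy(float),
            pred[t].to_numpy(float),
            config.r2_method,
        )
        for t in models_plsr
    }
    return {
        "trial": trial,
        "predictions": pred,
        "blup_results": results,
        "summary": table4,
        "r2_vs_truth": r2_vs_truth,
        "mask_counts": counts,
        "manifest": config.manifest(),
    }


def demo(seed: int = 1, outdir: str | Path | None = None,
         config: RunConfig | None = None) -> dict:
    """Full synthetic workflow: simulate, train, extrapolate, summarise."""
    t0 = time.time()
    if config is None:
        config = RunConfig(seed=seed)
    training = run_training(config)
    extrap = run_extrapolation(config, training["models_plsr"])
    report = {
        "manifest": config.manifest(),
        "training_summary": training["summary"],
        "extrapolation_summary": extrap["summary"],
        "r2_vs_truth": extrap["r2_vs_truth"],
        "n_curves_failed": training["n_curves_failed"],
        "n_outliers": training["n_outliers"],
        "index_subset": training["index_subset"],
        "elapsed_s": time.time() - t0,
        "_training": training,
        "_extrapolation": extrap,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        training["summary"].to_csv(outdir / "training_summary.csv", index=False)
        extrap["summary"].to_csv(outdir / "heritability_summary.csv", index=False)
        extrap["predictions"].to_csv(outdir / "trait_predictions.csv", index=False)
        fits = training["fit_table"].reset_index()
        fits.to_csv(outdir / "curve_fits.csv", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(
                {
                    **config.manifest(),
                    "r2_vs_truth": extrap["r2_vs_truth"],
                    "elapsed_s": report["elapsed_s"],
                },
                fh, indent=2,
            )
        for trait, m in training["models_plsr"].items():
            (outdir / f"plsr_{trait}.json").write_text(m.to_json())
    return report
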