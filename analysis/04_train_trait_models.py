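"""Train the two trait-prediction approaches on the training trial.

Approach 1: PCA-decorrelated vegetation-index subset + stepwise-AIC
multilinear regression.  Approach 2: full-spectrum PLSR with the
latent-variable count chosen by leave-one-out cross-validation.
Photosynthetic trait labels come from the curve fits (per-trait outlier
exclusion, Vcmax restricted to identifiable curves); SLN and LMA come
from the simulated leaf sampling.
"""

import sys
import warnings
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

from _shared import RESULTS, run_config

from c4spectra.chemometrics import fit_plsr, pca_index_subset, stepwise_aic
from c4spectra.curve_fitting import outlier_mask
from c4spectra.spectra import default_wavelengths


def main() -> None:
    warnings.simplefilter("ignore")
    config = run_config()
    X = pd.read_csv(RESULTS / "training_plot_reflectance.csv", index_col="plot_id")
    idx_tab = pd.read_csv(RESULTS / "training_indices.csv", index_col="plot_id")
    fits = pd.read_csv(RESULTS / "curve_fits.csv", index_col="plot_id")
    sampled = pd.read_csv(RESULTS / "sim" / "training_plot_traits.csv",
                          index_col="plot_id")

    labels = {}
    for t in ("Vcmax", "Vpmax", "Jmax"):
        keep = outlier_mask(fits[t], t)
        if t == "Vcmax":
            keep &= fits["vcmax_identifiable"].to_numpy(bool)
        labels[t] = fits.loc[keep, t]
    for t in ("SLN", "LMA"):
        labels[t] = sampled[t]

    subset = pca_index_subset(idx_tab, corr_threshold=config.corr_threshold)
    print(f"index subset ({len(subset.selected)} of {idx_tab.shape[1]}): "
          f"{subset.selected}; PC1-2 variance {subset.pc_variance[0]:.0f}%"
          f"+{subset.pc_variance[1]:.0f}%")

    rows = []
    models_dir = RESULTS / "models"
    models_dir.mkdir(parents=True, exist_ok=True)
    for trait, y in labels.items():
        common = y.index.intersection(X.index)
        plsr = fit_plsr(
            X.loc[common].to_numpy(), y.loc[common].to_numpy(),
            max_latent=config.max_latent, trait=trait,
            wavelengths=default_wavelengths(), r2_method=config.r2_method,
        )
        step = stepwise_aic(idx_tab.loc[common, subset.selected],
                            y.loc[common].to_numpy(), trait=trait)
        (models_dir / f"plsr_{trait}.json").write_text(plsr.to_json())
        rows.append(
            dict(trait=trait, n_plots=len(common), plsr_n_latent=plsr.n_latent,
                 plsr_cv_r2=plsr.cv_r2, plsr_cv_rmse=plsr.cv_rmse,
                 plsr_cv_rmse_pct=plsr.cv_rmse_pct,
                 plsr_insample_rmse=plsr.insample_rmse,
                 stepwise_indices=";".join(step.selected),
                 stepwise_r2=step.r2, stepwise_rmse=step.rmse)
        )
        print(f"{trait:6s} n={len(common):3d}  PLSR: {plsr.n_latent:2d} LVs, "
              f"CV R2 {plsr.cv_r2:.2f}, RMSE {plsr.cv_rmse:.3g} "
              f"({plsr.cv_rmse_pct:.1f}% of mean) | stepwise: "
              f"R2 {step.r2:.2f} [{','.join(step.selected) or 'intercept'}]")

    pd.DataFrame(rows).to_csv(RESULTS / "training_summary.csv", index=False)


if __name__ == "__main__":
    main()
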