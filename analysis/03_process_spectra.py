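"""NDVI-mask the canopy cubes of both trials and build index tables.

Cubes are regenerated deterministically from the seed, masked per pixel
at NDVI > 0.5, and averaged into one 272-band spectrum per plot; the
15-index vegetation table is computed from each plot spectrum.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

from _shared import RESULTS, run_config

from c4spectra.pipeline import _mask_cubes, index_table_for
from c4spectra.synthetic_data import GeneratorConfig, simulate_trial


def main() -> None:
    config = run_config()
    for label, gen in (
        ("training", GeneratorConfig(seed=config.seed,
                                     n_genotypes=config.n_train_genotypes,
                                     n_plots=config.n_train_plots)),
        ("target", GeneratorConfig(seed=config.seed + 500,
                                   n_genotypes=config.n_target_genotypes,
                                   n_plots=config.n_target_plots)),
    ):
        trial = simulate_trial(gen)
        X, wavelengths, counts = _mask_cubes(trial, config.mask_threshold)
        X.to_csv(RESULTS / f"{label}_plot_reflectance.csv")
        counts.to_csv(RESULTS / f"{label}_mask_counts.csv", index=False)
        idx = index_table_for(X, trial, config)
        idx.to_csv(RESULTS / f"{label}_indices.csv")
        frac = counts["n_plant"].sum() / counts["n_total"].sum()
        print(f"{label}: {len(X)} plots masked, "
              f"{frac:.1%} of pixels retained as plant")


if __name__ == "__main__":
    main()
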