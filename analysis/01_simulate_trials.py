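"""Simulate the training trial and the larger target (GWAS-style) trial.

Writes genotype truth, field layouts, plot-level trait values and the
gas-exchange curves of the training trial.  Spectra are regenerated
on demand by the later drivers (they are deterministic under the seed),
so only tabular artifacts are stored.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

from _shared import RESULTS, run_config

from c4spectra.curves import write_curves_csv
from c4spectra.synthetic_data import GeneratorConfig, simulate_trial


def main() -> None:
    config = run_config()
    out = RESULTS / "sim"
    out.mkdir(parents=True, exist_ok=True)

    training = simulate_trial(
        GeneratorConfig(seed=config.seed, n_genotypes=config.n_train_genotypes,
                        n_plots=config.n_train_plots)
    )
    target = simulate_trial(
        GeneratorConfig(seed=config.seed + 500,
                        n_genotypes=config.n_target_genotypes,
                        n_plots=config.n_target_plots)
    )

    training.truth.to_csv(out / "training_truth.csv", index=False)
    training.plot_traits.to_csv(out / "training_plot_traits.csv", index=False)
    target.truth.to_csv(out / "target_truth.csv", index=False)
    target.plot_traits.to_csv(out / "target_plot_traits.csv", index=False)
    target.layout.to_csv(out / "target_layout.csv", index=False)
    write_curves_csv(training.curves(), out / "training_curves.csv")

    print(f"training trial: {len(training.plot_traits)} plots, "
          f"{training.truth.shape[0]} genotypes")
    print(f"target trial:   {len(target.plot_traits)} plots, "
          f"{target.truth.shape[0]} genotypes")
    print(f"wrote tabular artifacts to {out}")


if __name__ == "__main__":
    main()
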