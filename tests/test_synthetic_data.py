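"""Synthetic trial generator: determinism, calibration, exact contracts."""

import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

from c4spectra.c4_model import LeafEnvironment, LeafPhotoParams, light_limited_A
from c4spectra.curves import ACI_CO2_STEPS
from c4spectra.spectra import mask_and_average, nearest_band
from c4spectra.synthetic_data import (
    TRAITS,
    GeneratorConfig,
    gen_field_layout,
    gen_genotype_truth,
    gen_plot_traits,
    plant_endmember,
    simulate_cube,
    simulate_curves,
    simulate_trial,
)


def small_config(**kw):
    base = dict(seed=7, n_genotypes=30, n_plots=40)
    base.update(kw)
    return GeneratorConfig(**base)


class TestGenotypeTruth:
    def test_same_seed_identical(self):
        cfg = small_config()
        pd.testing.assert_frame_equal(gen_genotype_truth(cfg), gen_genotype_truth(cfg))

    def test_sln_identity_exact(self):
        truth = gen_genotype_truth(small_config())
        np.testing.assert_allclose(
            truth["SLN"], truth["pct_N"] / 100.0 * truth["LMA"], rtol=1e-12
        )

    def test_mean_calibration_at_large_n(self):
        cfg = GeneratorConfig(seed=11, n_genotypes=1000, n_plots=1000)
        truth = gen_genotype_truth(cfg)
        assert truth["Vcmax"].mean() == pytest.approx(51.1, abs=2.0)
        assert truth["LMA"].mean() == pytest.approx(50.0, abs=2.0)

    def test_zero_genetic_sd_gives_identical_genotypes(self):
        cfg = small_config()
        cfg = cfg.model_copy(update={"genetic_sd": {t: 1e-12 for t in TRAITS}})
        truth = gen_genotype_truth(cfg)
        assert truth["Vcmax"].std() < 1e-6

    def test_all_traits_positive(self):
        truth = gen_genotype_truth(GeneratorConfig(seed=3, n_genotypes=500,
                                                   n_plots=500))
        assert (truth[TRAITS] > 0).all().all()

    def test_non_psd_correlation_rejected(self):
        bad = np.full((5, 5), 0.99)
        np.fill_diagonal(bad, 1.0)
        bad[0, 1] = bad[1, 0] = -0.99
        with pytest.raises(ValidationError):
            small_config(trait_corr=bad.tolist())


class TestFieldLayout:
    def test_reference_trial_shape(self):
        cfg = GeneratorConfig(seed=1, n_genotypes=650, n_plots=875)
        layout = gen_field_layout(cfg)
        assert len(layout) == 875
        assert layout["genotype"].nunique() == 650

    def test_positions_unique_and_complete(self):
        layout = gen_field_layout(small_config())
        assert not layout.duplicated(subset=["row", "col"]).any()
        assert layout["genotype"].notna().all()

    def test_no_replication_means_plots_equal_genotypes(self):
        cfg = GeneratorConfig(seed=2, n_genotypes=25, n_plots=25)
        layout = gen_field_layout(cfg)
        assert layout["genotype"].nunique() == 25
        assert (layout.groupby("genotype").size() == 1).all()


class TestCurves:
    def test_aci_uses_reference_co2_sequence(self):
        trial = simulate_trial(small_config(n_genotypes=2, n_plots=2))
        aci = next(c for c in trial.curves(noise_cv=0.0) if c.kind == "ACi")
        assert list(aci.Ca) == list(ACI_CO2_STEPS)
        assert np.all(aci.I_inc == 1800.0)

    def test_noise_free_reproducible_by_forward_model(self):
        """The noise-free backbone is the forward model itself."""
        from c4spectra.c4_model import net_assimilation

        cfg = small_config(n_genotypes=2, n_plots=2)
        trial = simulate_trial(cfg)
        row = trial.plot_traits.iloc[0]
        params = LeafPhotoParams(
            Vcmax=row["Vcmax"], Vpmax=row["Vpmax"], Jmax=row["Jmax"],
            Rd=cfg.rd_true, theta=cfg.theta_true, PSabs=cfg.psabs_true,
        )
        curves = simulate_curves(trial.plot_traits.iloc[[0]], "both", 0.0, 5, cfg)
        aci = next(c for c in curves if c.kind == "ACi")
        for step in aci.steps:
            env = LeafEnvironment(Ca=step.Ca, I_inc=step.I_inc, Ci=step.Ci)
            assert step.A_obs == pytest.approx(net_assimilation(env, params).A,
                                               abs=1e-10)
        ai = next(c for c in curves if c.kind == "Ai")
        for step in ai.steps:
            env = LeafEnvironment(Ca=step.Ca, I_inc=step.I_inc, Ci=step.Ci)
            expected = (-params.Rd if step.I_inc == 0
                        else light_limited_A(env, params))
            assert step.A_obs == pytest.approx(expected, abs=1e-10)

    def test_seeds_change_noise_not_backbone(self):
        cfg = small_config(n_genotypes=2, n_plots=2)
        trial = simulate_trial(cfg)
        one = trial.plot_traits.iloc[[0]]
        a = simulate_curves(one, "ACi", 0.02, 1, cfg)[0].A_obs
        b = simulate_curves(one, "ACi", 0.02, 2, cfg)[0].A_obs
        clean1 = simulate_curves(one, "ACi", 0.0, 1, cfg)[0].A_obs
        clean2 = simulate_curves(one, "ACi", 0.0, 2, cfg)[0].A_obs
        assert not np.allclose(a, b)
        np.testing.assert_allclose(clean1, clean2)


class TestCubes:
    def test_zero_soil_fraction_retains_every_pixel(self):
        cfg = small_config(soil_fraction=0.0, pixels_per_plot=30)
        trial = simulate_trial(cfg)
        cube = simulate_cube(trial.plot_traits.iloc[0], cfg, seed=9)
        pr = mask_and_average(cube)
        assert pr.n_plant_pixels == pr.n_total_pixels == 30

    def test_constructed_membership_recovered_by_mask(self):
        cfg = small_config(soil_fraction=0.25, pixels_per_plot=80)
        trial = simulate_trial(cfg)
        cube = simulate_cube(trial.plot_traits.iloc[0], cfg, seed=9)
        pr = mask_and_average(cube)
        assert pr.n_plant_pixels == 60
        assert pr.n_total_pixels == 80

    def test_deeper_red_trough_with_higher_sln(self):
        cfg = small_config()
        base = {"Vcmax": 51.1, "Vpmax": 408.0, "Jmax": 409.0, "LMA": 50.0}
        r670 = []
        for sln in (1.6, 2.0, 2.4):
            row = pd.Series({**base, "SLN": sln})
            endm = plant_endmember(row, cfg)
            from c4spectra.spectra import default_wavelengths

            r670.append(endm[nearest_band(default_wavelengths(), 670.0)])
        assert r670[0] > r670[1] > r670[2]

    def test_cube_deterministic_under_seed(self):
        cfg = small_config()
        trial = simulate_trial(cfg)
        c1 = simulate_cube(trial.plot_traits.iloc[0], cfg, seed=42)
        c2 = simulate_cube(trial.plot_traits.iloc[0], cfg, seed=42)
        np.testing.assert_array_equal(c1.pixels, c2.pixels)


def test_plot_traits_keep_sln_identity():
    cfg = small_config()
    trial = simulate_trial(cfg)
    pt = trial.plot_traits
    np.testing.assert_allclose(pt["SLN"], pt["pct_N"] / 100.0 * pt["LMA"],
                               rtol=1e-12)
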