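"""Synthetic field-trial generator for desk-scale pipeline exercises.

Emulates, with stated distributions, every input the pipeline needs:

* genotype truth values for the five traits (Vcmax, Vpmax, Jmax, SLN,
  LMA) drawn from a correlated multivariate normal with separate genetic
  and plot-residual variances, calibrated to published field summaries
  (Vcmax mean ~51 umol m-2 s-1 ranging ~40-65, Vpmax ~408, Jmax ~409,
  SLN ~2.0 g m-2, LMA ~36-64 g m-2);
* partially replicated row-column field layouts;
* ACi and Ai gas-exchange curves forward-simulated by the C4 model at
  the standard protocol steps, with multiplicative noise (CV ~2%) plus
  an additive instrument floor (SD 0.2 umol m-2 s-1);
* plant+soil pixel spectra whose plant endmember varies with the traits:
  the chlorophyll trough near 670 nm deepens with SLN, the red-edge
  inflection shifts with SLN (mildly nonlinear) and steepens with Jmax,
  the NIR plateau scales with LMA (and weakly Vcmax), and a structural
  dip near 955 nm scales with LMA; Vcmax and Vpmax add narrow features
  near 531 and 600 nm.  Plant pixels have NDVI > 0.6 by construction and
  the flat soil endmember has NDVI < 0.2, so NDVI masking is exact.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator, Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.ndimage import gaussian_filter1d

from .c4_model import (
    C4Constants,
    LeafEnvironment,
    LeafPhotoParams,
    NonPhysicalWarning,
    light_limited_A,
    net_assimilation,
)
from .curves import (
    ACI_CO2_STEPS,
    ACI_LIGHT,
    AI_CO2,
    AI_LIGHT_STEPS,
    CurveStep,
    ResponseCurve,
)
from .spectra import SpectralCube, default_wavelengths

__all__ = [
    "TRAITS",
    "GeneratorConfig",
    "default_trait_correlation",
    "gen_genotype_truth",
    "gen_field_layout",
    "gen_plot_traits",
    "simulate_curves",
    "plant_endmember",
    "simulate_cube",
    "SimulatedTrial",
    "simulate_trial",
]

TRAITS = ["Vcmax", "Vpmax", "Jmax", "SLN", "LMA"]


def default_trait_correlation() -> np.ndarray:
    """Genotype-level trait correlation: Vcmax-SLN 0.6, Jmax-SLN 0.5, rest 0.2."""
    r = np.full((5, 5), 0.2)
    np.fill_diagonal(r, 1.0)
    i = {t: k for k, t in enumerate(TRAITS)}
    for a, b, v in [("Vcmax", "SLN", 0.6), ("Jmax", "SLN", 0.5)]:
        r[i[a], i[b]] = r[i[b], i[a]] = v
    return r


class GeneratorConfig(BaseModel):
    """Study conditions of the synthetic trial (seed is mandatory)."""

    seed: int
    n_genotypes: int = 650
    n_plots: int = 875
    trait_means: dict[str, float] = Field(
        default_factory=lambda: {
            "Vcmax": 51.1, "Vpmax": 408.0, "Jmax": 409.0, "SLN": 2.0, "LMA": 50.0,
        }
    )
    genetic_sd: dict[str, float] = Field(
        default_factory=lambda: {
            "Vcmax": 4.5, "Vpmax": 90.0, "Jmax": 70.0, "SLN": 0.22, "LMA": 5.5,
        }
    )
    residual_sd: dict[str, float] = Field(
        default_factory=lambda: {
            "Vcmax": 2.0, "Vpmax": 40.0, "Jmax": 32.0, "SLN": 0.10, "LMA": 2.5,
        }
    )
    # gas exchange
    curve_noise_cv: float = 0.02
    curve_noise_floor: float = 0.2   # umol m-2 s-1
    ci_over_ca: float = 0.4
    ci_jitter_sd: float = 0.02       # SD of the Ci/Ca ratio jitter
    rd_true: float = 2.0
    theta_true: float = 0.3
    # fraction of incident light absorbed and useful to PSII; ~0.85 leaf
    # absorptance x ~0.5 PSII share.  Keeps the transport ceiling above the
    # Rubisco plateau at saturating CO2, matching the observed fittability
    # of field ACi curves at these trait magnitudes.
    psabs_true: float = 0.45
    # spectra
    # optional override of the 5x5 genotype trait correlation (TRAITS order)
    trait_corr: list[list[float]] | None = None
    n_bands: int = 272
    pixels_per_plot: int = 80
    soil_fraction: float = 0.25
    pixel_noise_sd: float = 0.008
    endmember_noise_sd: float = 0.003
    brightness_sd: float = 0.06
    soil_reflectance: float = 0.25

    @model_validator(mode="after")
    def _check(self):
        for d in (self.trait_means, self.genetic_sd, self.residual_sd):
            if set(d) != set(TRAITS):
                raise ValueError(f"trait dict must have keys {TRAITS}")
        if self.n_plots < self.n_genotypes:
            raise ValueError("n_plots must be >= n_genotypes")
        ev = np.linalg.eigvalsh(self.correlation())
        if ev.min() < -1e-10:
            raise ValueError("trait correlation matrix is not positive semi-definite")
        return self

    def correlation(self) -> np.ndarray:
        if self.trait_corr is not None:
            r = np.asarray(self.trait_corr, float)
            if r.shape != (5, 5):
                raise ValueError("trait_corr must be 5x5 in TRAITS order")
            return r
        return default_trait_correlation()

    def total_sd(self, trait: str) -> float:
        return float(np.hypot(self.genetic_sd[trait], self.residual_sd[trait]))


def gen_genotype_truth(config: GeneratorConfig) -> pd.DataFrame:
    """Correlated genotype truth values, truncated to positive.

    SLN = (%N / 100) x LMA holds exactly: SLN and LMA are drawn and
    percent nitrogen is derived.
    """
    rng = np.random.default_rng(config.seed)
    mu = np.array([config.trait_means[t] for t in TRAITS])
    sd = np.array([config.genetic_sd[t] for t in TRAITS])
    L = np.linalg.cholesky(config.correlation() + 1e-12 * np.eye(5))
    vals = np.empty((config.n_genotypes, 5))
    for i in range(config.n_genotypes):
        for _ in range(100):
            v = mu + sd * (L @ rng.standard_normal(5))
            if (v > 0).all():
                break
        else:
            raise RuntimeError("could not draw positive trait vector")
        vals[i] = v
    df = pd.DataFrame(vals, columns=TRAITS)
    df.insert(0, "genotype", [f"g{i:04d}" for i in range(config.n_genotypes)])
    df["pct_N"] = df["SLN"] / df["LMA"] * 100.0
    return df


def gen_field_layout(config: GeneratorConfig) -> pd.DataFrame:
    """Partially replicated row-column layout.

    Every genotype appears once; the remaining plots repeat a random
    subset of genotypes.  Positions are randomised by the seed.
    """
    rng = np.random.default_rng(config.seed + 1)
    n_rows = int(np.floor(np.sqrt(config.n_plots)))
    n_cols = int(np.ceil(config.n_plots / n_rows))
    if n_rows * n_cols < config.n_plots:
        raise ValueError("grid too small for requested plot count")
    genos = [f"g{i:04d}" for i in range(config.n_genotypes)]
    extra_n = config.n_plots - config.n_genotypes
    extra = list(
        rng.choice(genos, size=extra_n, replace=extra_n > config.n_genotypes)
    )
    assignment = np.array(genos + extra)
    rng.shuffle(assignment)
    rows, cols = np.divmod(np.arange(config.n_plots), n_cols)
    df = pd.DataFrame(
        {
            "plot_id": [f"p{i:04d}" for i in range(config.n_plots)],
            "genotype": assignment,
            "row": rows + 1,
            "col": cols + 1,
        }
    )
    df["replicate"] = df.groupby("genotype").cumcount() + 1
    return df


def gen_plot_traits(truth: pd.DataFrame, layout: pd.DataFrame,
                    config: GeneratorConfig) -> pd.DataFrame:
    """Plot-level trait values = genotype truth + independent residuals.

    Residuals perturb SLN and LMA directly and %N is re-derived, so the
    SLN = (%N/100) x LMA identity survives at plot level.
    """
    rng = np.random.default_rng(config.seed + 2)
    df = layout.merge(truth, on="genotype", how="left")
    for t in TRAITS:
        noise = rng.normal(0.0, config.residual_sd[t], size=len(df))
        df[t] = np.maximum(df[t] + noise, 1e-3)
    df["pct_N"] = df["SLN"] / df["LMA"] * 100.0
    return df


def _true_params(row, config: GeneratorConfig) -> LeafPhotoParams:
    return LeafPhotoParams(
        Vcmax=float(row["Vcmax"]), Vpmax=float(row["Vpmax"]),
        Jmax=float(row["Jmax"]), Rd=config.rd_true,
        theta=config.theta_true, PSabs=config.psabs_true,
    )


def simulate_curves(truth: pd.DataFrame, protocol: Literal["ACi", "Ai", "both"],
                    noise_cv: float, seed: int,
                    config: GeneratorConfig | None = None,
                    consts: C4Constants = C4Constants()) -> list[ResponseCurve]:
    """Forward-simulated gas-exchange curves at the standard protocols.

    Each observed A is the model prediction at the (jittered) step
    conditions times (1 + N(0, noise_cv)) plus N(0, floor).  With
    noise_cv = 0 every stochastic element is off and ACi curves
    reproduce :func:`c4spectra.c4_model.predict_curve` exactly.

    ACi observations come from the full min(Ac, Aj) model.  Ai
    observations come from the electron-transport-limited branch alone:
    the light-response protocol at ambient CO2 is designed to trace that
    branch, and it is the model the downstream Ai fit inverts, so the
    generated leaf is transport-limited across the light steps.
    """
    if config is None:
        config = GeneratorConfig(seed=seed)
    rng = np.random.default_rng(seed)
    kinds = ["ACi", "Ai"] if protocol == "both" else [protocol]
    curves = []
    for _, row in truth.iterrows():
        params = _true_params(row, config)
        for kind in kinds:
            if kind == "ACi":
                steps_env = [(float(ca), ACI_LIGHT) for ca in ACI_CO2_STEPS]
            else:
                steps_env = [(AI_CO2, float(i)) for i in AI_LIGHT_STEPS]
            steps = []
            for ca, i_inc in steps_env:
                ratio = config.ci_over_ca
                if noise_cv > 0:
                    ratio = float(
                        np.clip(ratio + rng.normal(0, config.ci_jitter_sd),
                                0.05, 0.95)
                    )
                env = LeafEnvironment(Ca=ca, I_inc=i_inc, Ci=ca * ratio)
                with warnings.catch_warnings():
                    # the non-binding branch of min(Ac, Aj) routinely
                    # overshoots the CO2 supply at low Ca
                    warnings.simplefilter("ignore", NonPhysicalWarning)
                    if kind == "Ai":
                        a = (-params.Rd if i_inc == 0
                             else light_limited_A(env, params, consts))
                    else:
                        a = net_assimilation(env, params, consts).A
                if noise_cv > 0:
                    a = a * (1.0 + rng.normal(0, noise_cv)) + rng.normal(
                        0, config.curve_noise_floor
                    )
                steps.append(CurveStep(A_obs=a, Ca=ca, Ci=env.ci, I_inc=i_inc))
            curves.append(
                ResponseCurve(
                    kind=kind, steps=steps,
                    plot_id=str(row.get("plot_id", row.get("genotype", ""))),
                    genotype=str(row.get("genotype", "")),
                )
            )
    return curves


def _z(row, trait: str, config: GeneratorConfig) -> float:
    z = (float(row[trait]) - config.trait_means[trait]) / config.total_sd(trait)
    return float(np.clip(z, -2.5, 2.5))


def plant_endmember(row, config: GeneratorConfig,
                    wavelengths: np.ndarray | None = None) -> np.ndarray:
    """Deterministic green-canopy spectrum implied by one plot's traits."""
    w = default_wavelengths(config.n_bands) if wavelengths is None else wavelengths
    zv = _z(row, "Vcmax", config)
    zp = _z(row, "Vpmax", config)
    zj = _z(row, "Jmax", config)
    zs = _z(row, "SLN", config)
    zl = _z(row, "LMA", config)

    vis = 0.09 + 0.06 * np.exp(-((w - 550.0) ** 2) / (2 * 28.0**2))
    trough = (0.030 + 0.010 * zs) * np.exp(-((w - 670.0) ** 2) / (2 * 35.0**2))
    amp = 0.42 + 0.035 * zl + 0.025 * zv
    lam0 = 716.0 + 3.0 * np.tanh(0.5 * zs)
    slope = max(14.0 - 1.5 * zj, 9.0)
    red_edge = amp / (1.0 + np.exp(-(w - lam0) / slope))
    dip531 = 0.025 * zv * np.exp(-((w - 531.0) ** 2) / (2 * 9.0**2))
    bump600 = 0.018 * zp * np.exp(-((w - 600.0) ** 2) / (2 * 14.0**2))
    # NIR plateau bump at 870 nm: electron-transport capacity signal placed
    # away from the wavelengths the index set samples, so the full spectrum
    # carries information the 15 indices cannot
    bump870 = 0.014 * zj * np.exp(-((w - 870.0) ** 2) / (2 * 15.0**2))
    dip955 = (0.035 + 0.010 * zl) * np.exp(-((w - 955.0) ** 2) / (2 * 14.0**2))
    r = vis + red_edge - trough - dip531 + bump600 + bump870 - dip955
    return np.clip(r, 1e-3, 1.4)


def _smooth_noise(rng, n: int, sigma_bands: float, sd: float) -> np.ndarray:
    """Band-correlated Gaussian noise with unit-calibrated amplitude."""
    raw = gaussian_filter1d(rng.standard_normal(n), sigma_bands, mode="nearest")
    s = raw.std()
    return sd * raw / s if s > 0 else np.zeros(n)


def simulate_cube(truth_row, config: GeneratorConfig, seed: int) -> SpectralCube:
    """Mixed plant/soil pixel cube for one plot.

    Plant pixels share the trait-driven endmember (plus one plot-level
    smooth perturbation) scaled by per-pixel brightness, with
    band-correlated pixel noise; soil pixels are spectrally flat near
    ``soil_reflectance`` with a small slope.
    """
    rng = np.random.default_rng(seed)
    w = default_wavelengths(config.n_bands)
    n_soil = int(round(config.pixels_per_plot * config.soil_fraction))
    n_plant = config.pixels_per_plot - n_soil

    base = plant_endmember(truth_row, config, w)
    base = base + _smooth_noise(rng, w.size, 15.0, config.endmember_noise_sd)

    pixels = np.empty((config.pixels_per_plot, w.size))
    for k in range(n_plant):
        bright = np.exp(rng.normal(0.0, config.brightness_sd))
        pixels[k] = base * bright + _smooth_noise(
            rng, w.size, 4.0, config.pixel_noise_sd
        )
    soil = config.soil_reflectance + 3e-5 * (w - w.mean())
    for k in range(n_plant, config.pixels_per_plot):
        pixels[k] = soil + _smooth_noise(rng, w.size, 4.0, config.pixel_noise_sd)
    pixels = np.clip(pixels, 1e-4, 1.4)
    side = int(np.ceil(np.sqrt(config.pixels_per_plot)))
    coords = np.column_stack(
        np.divmod(np.arange(config.pixels_per_plot), side)
    )
    return SpectralCube(
        wavelengths=w, pixels=pixels,
        plot_id=str(truth_row.get("plot_id", "")), coords=coords,
    )


@dataclass
class SimulatedTrial:
    """Bundled outputs of one simulated trial."""

    config: GeneratorConfig
    truth: pd.DataFrame        # genotype-level
    layout: pd.DataFrame
    plot_traits: pd.DataFrame  # layout + plot-level trait values

    def iter_cubes(self) -> Iterator[SpectralCube]:
        for i, (_, row) in enumerate(self.plot_traits.iterrows()):
            yield simulate_cube(row, self.config, self.config.seed + 1000 + i)

    def curves(self, noise_cv: float | None = None) -> list[ResponseCurve]:
        cv = self.config.curve_noise_cv if noise_cv is None else noise_cv
        return simulate_curves(
            self.plot_traits, "both", cv, self.config.seed + 3, self.config
        )


def simulate_trial(config: GeneratorConfig) -> SimulatedTrial:
    """Genotype truth -> layout -> plot traits, fully seeded."""
    truth = gen_genotype_truth(config)
    layout = gen_field_layout(config)
    plot_traits = gen_plot_traits(truth, layout, config)
    return SimulatedTrial(config, truth, layout, plot_traits)
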