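"""Canopy hyperspectral processing: NDVI masking and vegetation indices.

Plot spectra come from a pushbroom imager with 272 bands spanning roughly
395-997 nm (~2.2 nm sampling).  Per pixel, NDVI = (p800 - p670)/(p800 + p670)
separates green canopy from soil/shadow background; pixels with NDVI
strictly greater than 0.5 are retained and averaged per band to give the
plot reflectance.  From the plot spectrum a set of 15 vegetation indices
associated with chlorophyll, leaf area and photosynthetic efficiency is
computed.  Index formulas name nominal wavelengths; sensor bands are
resolved by nearest wavelength, no interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "N_BANDS",
    "INDEX_NAMES",
    "default_wavelengths",
    "SpectralCube",
    "PlotReflectance",
    "nearest_band",
    "pixel_ndvi",
    "mask_and_average",
    "compute_indices",
    "index_table",
]

N_BANDS = 272


def default_wavelengths(n_bands: int = N_BANDS, lo: float = 395.0,
                        hi: float = 997.0) -> np.ndarray:
    """Evenly spaced band centres over the sensor's spectral range (nm)."""
    return np.linspace(lo, hi, n_bands)


@dataclass
class SpectralCube:
    """Pixel spectra of one plot (n_pixels x n_bands reflectance)."""

    wavelengths: np.ndarray
    pixels: np.ndarray
    plot_id: str = ""
    coords: np.ndarray | None = None  # (n_pixels, 2) row/col, optional

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.pixels = np.atleast_2d(np.asarray(self.pixels, dtype=float))
        if self.pixels.shape[1] != self.wavelengths.size:
            raise ValueError("pixel matrix width must match wavelength count")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(self.pixels < 0):
            raise ValueError("negative reflectance in cube")

    @property
    def n_pixels(self) -> int:
        return self.pixels.shape[0]


@dataclass
class PlotReflectance:
    """NDVI-masked plot-mean spectrum with retention bookkeeping."""

    wavelengths: np.ndarray
    reflectance: np.ndarray | None
    n_plant_pixels: int
    n_total_pixels: int
    plot_id: str = ""
    empty: bool = False
    low_fraction: bool = False

    @property
    def plant_fraction(self) -> float:
        if self.n_total_pixels == 0:
            return 0.0
        return self.n_plant_pixels / self.n_total_pixels


def nearest_band(wavelengths: Sequence[float], nominal: float) -> int:
    """Index of the band closest to a nominal wavelength (ties -> lower)."""
    w = np.asarray(wavelengths, dtype=float)
    if nominal < w[0] - 5.0 or nominal > w[-1] + 5.0:
        raise ValueError(
            f"nominal wavelength {nominal} nm outside sensor range "
            f"[{w[0]}, {w[-1]}] +/- 5 nm"
        )
    d = np.abs(w - nominal)
    return int(np.flatnonzero(d == d.min())[0])


def pixel_ndvi(cube: SpectralCube) -> np.ndarray:
    """Per-pixel NDVI from the bands nearest 800 and 670 nm."""
    nir = cube.pixels[:, nearest_band(cube.wavelengths, 800.0)]
    red = cube.pixels[:, nearest_band(cube.wavelengths, 670.0)]
    den = nir + red
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(den == 0, 0.0, (nir - red) / np.where(den == 0, 1.0, den))
    return ndvi


def mask_and_average(cube: SpectralCube, threshold: float = 0.5,
                     min_fraction: float = 0.01) -> PlotReflectance:
    """Retain pixels with NDVI strictly above threshold; average per band.

    Zero retained pixels yields an empty-plot result (reflectance None);
    a retained fraction below ``min_fraction`` raises a warning flag but
    keeps the mean.
    """
    if cube.n_pixels == 0:
        raise ValueError("empty cube")
    keep = pixel_ndvi(cube) > threshold
    n_keep = int(keep.sum())
    if n_keep == 0:
        return PlotReflectance(
            wavelengths=cube.wavelengths, reflectance=None,
            n_plant_pixels=0, n_total_pixels=cube.n_pixels,
            plot_id=cube.plot_id, empty=True,
        )
    low = n_keep / cube.n_pixels < min_fraction
    return PlotReflectance(
        wavelengths=cube.wavelengths,
        reflectance=cube.pixels[keep].mean(axis=0),
        n_plant_pixels=n_keep,
        n_total_pixels=cube.n_pixels,
        plot_id=cube.plot_id,
        low_fraction=low,
    )


INDEX_NAMES = [
    "Curvature", "CVI", "NDRE", "NDVI", "PRI",
    "r685_r655", "r690_r600", "r740_r700", "r760_r750", "r760_r750index",
    "Red_edge", "OSAVI", "r750", "r760", "TVI",
]


def _safe_div(num: float, den: float) -> float:
    return float("nan") if den == 0 else num / den


def compute_indices(pr: PlotReflectance) -> dict[str, float]:
    """Vegetation indices of one plot spectrum.

    Normalized-difference indices: NDVI (800/670), NDRE (750/710),
    PRI (531/570), r760_r750index; simple ratios r685/r655, r690/r600,
    r740/r700, r760/r750, Red_edge = p750/p710; Curvature =
    p683^2/(p675 p690); CVI = (p750/p550)(p670/p550); OSAVI =
    1.16 (p800-p670)/(p800+p670+0.16); raw bands r750, r760; and
    TVI = 0.5[120(p750-p550) - 200(p670-p550)].  A zero denominator
    reports NaN for that index.
    """
    if pr.reflectance is None:
        raise ValueError("plot has no retained plant pixels")
    w = pr.wavelengths

    def p(nm: float) -> float:
        return float(pr.reflectance[nearest_band(w, nm)])

    p531, p550, p570, p600 = p(531), p(550), p(570), p(600)
    p655, p670, p675, p683 = p(655), p(670), p(675), p(683)
    p685, p690, p700, p710 = p(685), p(690), p(700), p(710)
    p740, p750, p760, p800 = p(740), p(750), p(760), p(800)

    return {
        "Curvature": _safe_div(p683**2, p675 * p690),
        "CVI": _safe_div(p750, p550) * _safe_div(p670, p550),
        "NDRE": _safe_div(p750 - p710, p750 + p710),
        "NDVI": _safe_div(p800 - p670, p800 + p670),
        "PRI": _safe_div(p531 - p570, p531 + p570),
        "r685_r655": _safe_div(p685, p655),
        "r690_r600": _safe_div(p690, p600),
        "r740_r700": _safe_div(p740, p700),
        "r760_r750": _safe_div(p760, p750),
        "r760_r750index": _safe_div(p760 - p750, p760 + p750),
        "Red_edge": _safe_div(p750, p710),
        "OSAVI": 1.16 * _safe_div(p800 - p670, p800 + p670 + 0.16),
        "r750": p750,
        "r760": p760,
        "TVI": 0.5 * (120.0 * (p750 - p550) - 200.0 * (p670 - p550)),
    }


def index_table(plots: Iterable[PlotReflectance]) -> pd.DataFrame:
    """Index rows for a set of plots (empty plots skipped with a warning)."""
    rows, ids = [], []
    for pr in plots:
        if pr.empty or pr.reflectance is None:
            warnings.warn(f"plot {pr.plot_id}: no plant pixels, skipped")
            continue
        rows.append(compute_indices(pr))
        ids.append(pr.plot_id)
    return pd.DataFrame(rows, index=pd.Index(ids, name="plot_id"))[INDEX_NAMES]
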