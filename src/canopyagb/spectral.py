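"""Plot-mean reflectance spectra and the 15 canopy vegetation indices.

Indices are computed on the ROI-mean spectrum (the mean reflectance of the
plot polygon is extracted first, then the index formula is applied), which
matches the plot-zonal workflow this pipeline models; a per-pixel mode
(:func:`vi_map`) exists for map rendering only.

Band symbols such as R800 resolve to the nearest cube band via
:func:`canopyagb.geo.band_at`.  The four RGB-letter indices (EXG, EXB,
NGBVI, NGBDI) originate from RGB imagery and default to orthomosaic
channels rescaled to [0, 1]; when no RGB raster is supplied they fall back
to the cube bands nearest 660/550/480 nm.

A zero denominator yields a missing value (NaN), counted and logged, never
an exception: soil-only plots must not abort a campaign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from canopyagb.geo import HyperspectralCube, PlotROI, RasterGrid, band_at, rasterize_roi

log = logging.getLogger(__name__)

__all__ = [
    "VI_NAMES",
    "RGB_VI_NAMES",
    "ReflectanceSpectrum",
    "mean_roi_spectrum",
    "compute_vi",
    "vi_table",
    "vi_map",
]


@dataclass
class ReflectanceSpectrum:
    """Mean canopy reflectance of one plot."""

    wavelengths_nm: np.ndarray
    reflectance: np.ndarray
    plot_id: str = ""
    stage: str | None = None

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths_nm.shape != self.reflectance.shape:
            raise ValueError("wavelength and reflectance arrays differ in length")

    def at(self, wavelength_nm: float):
        return self.reflectance[band_at(self.wavelengths_nm, wavelength_nm)]


def _div(num, den):
    """Division with zero denominators mapped to NaN (missing)."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.full(np.broadcast_shapes(num.shape, den.shape), np.nan)
    np.divide(num, den, out=out, where=den != 0)
    if out.ndim == 0:
        return float(out)
    return out


# Each hyperspectral index: (wavelengths used, formula over the resolved bands).
CUBE_VI = {
    "NDVI": ((800, 680), lambda R: _div(R[800] - R[680], R[800] + R[680])),
    "RVI": ((810, 660), lambda R: _div(R[810], R[660])),
    "EVI": ((800, 670, 450),
            lambda R: 2.5 * _div(R[800] - R[670],
                                 R[800] + 6.0 * R[670] - 7.5 * R[450] + 1.0)),
    "SPVI": ((800, 670, 550),
             lambda R: 0.4 * (3.7 * (R[800] - R[670])
                              - 1.2 * np.abs(R[550] - R[670]))),
    "MCARI": ((700, 670, 550),
              lambda R: ((R[700] - R[670]) - 0.2 * (R[700] - R[550]))
              * _div(R[700], R[670])),
    "RNDVI": ((800, 670),
              lambda R: _div(R[800] - R[670],
                             np.sqrt(np.maximum(R[800] + R[670], 0.0)))),
    "CIrededge": ((810, 690), lambda R: _div(R[810], R[690]) - 1.0),
    "VARI": ((555, 680, 480),
             lambda R: _div(R[555] - R[680], R[555] + R[680] - R[480])),
    "SAVI": ((800, 670),
             lambda R: 1.5 * _div(R[800] - R[670], R[800] + R[670] + 0.5)),
    "GNDVI": ((750, 550), lambda R: _div(R[750] - R[550], R[750] + R[550])),
    "SIPI": ((800, 450, 680), lambda R: _div(R[800] - R[450], R[800] + R[680])),
}

# RGB-letter indices over channels rescaled to [0, 1].
RGB_VI = {
    "EXG": lambda r, g, b: 2.0 * g - r - b,
    "EXB": lambda r, g, b: 1.4 * b - g,
    "NGBVI": lambda r, g, b: _div(g ** 2 - b * r, g ** 2 + b * r),
    "NGBDI": lambda r, g, b: _div(g - b, g + b),
}

# Cube-band fallback for the RGB letters (nearest red/green/blue centers).
RGB_FALLBACK_NM = {"R": 660, "G": 550, "B": 480}

RGB_VI_NAMES = tuple(RGB_VI)
VI_NAMES = (
    "NDVI", "RVI", "EXG", "EXB", "NGBVI", "NGBDI", "EVI", "SPVI", "MCARI",
    "RNDVI", "CIrededge", "VARI", "SAVI", "GNDVI", "SIPI",
)


def mean_roi_spectrum(cube: HyperspectralCube, mask: np.ndarray,
                      plot_id: str = "", stage: str | None = None,
                      ) -> ReflectanceSpectrum:
    """Arithmetic mean reflectance over the masked pixels, band by band.

    Negative reflectances and the grid's nodata sentinel are excluded from
    the mean (per band).  An all-invalid plot is an error.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError(f"plot {plot_id or '?'}: empty ROI mask")
    vals = cube.grid.values[:, mask].astype(float)  # bands x npix
    valid = np.isfinite(vals) & (vals >= 0)
    if cube.grid.nodata is not None:
        valid &= vals != cube.grid.nodata
    if not valid.any():
        raise ValueError(f"plot {plot_id or '?'}: all pixels are nodata")
    with np.errstate(invalid="ignore"):
        mean = np.where(valid, vals, 0.0).sum(axis=1) / valid.sum(axis=1)
    return ReflectanceSpectrum(wavelengths_nm=cube.wavelengths_nm,
                               reflectance=mean, plot_id=plot_id, stage=stage)


def compute_vi(spec: ReflectanceSpectrum, name: str,
               rgb: tuple[float, float, float] | None = None) -> float:
    """Evaluate one vegetation index on a plot-mean spectrum.

    ``rgb`` supplies the (R, G, B) reflectances in [0, 1] for the RGB-letter
    indices; if omitted they are taken from the spectrum at 660/550/480 nm.
    """
    if name in CUBE_VI:
        wls, fn = CUBE_VI[name]
        return float(fn({w: spec.at(w) for w in wls}))
    if name in RGB_VI:
        if rgb is None:
            rgb = tuple(spec.at(RGB_FALLBACK_NM[ch]) for ch in "RGB")
        return float(RGB_VI[name](*map(float, rgb)))
    raise KeyError(f"unknown vegetation index {name!r}")


def _mean_rgb(rgb: RasterGrid, mask: np.ndarray) -> tuple[float, float, float]:
    vals = rgb.values.astype(float)
    if vals.ndim != 3 or vals.shape[0] != 3:
        raise ValueError("RGB raster must have 3 bands")
    scale = 255.0 if np.issubdtype(rgb.values.dtype, np.integer) else 1.0
    return tuple(float(vals[i][mask].mean() / scale) for i in range(3))


def vi_table(cube: HyperspectralCube, plots: list[PlotROI],
             rgb: RasterGrid | None = None) -> pd.DataFrame:
    """One row per plot with all 15 index columns.

    RGB-letter indices use ``rgb`` (plot-mean channels / 255) when given,
    the cube fallback bands otherwise.
    """
    rows = []
    n_missing = 0
    for roi in plots:
        mask = rasterize_roi(roi, cube.grid)
        spec = mean_roi_spectrum(cube, mask, plot_id=roi.plot_id, stage=roi.stage)
        rgb_mean = _mean_rgb(rgb, mask) if rgb is not None else None
        rec = {"plot_id": roi.plot_id, "stage": roi.stage}
        for name in VI_NAMES:
            v = compute_vi(spec, name, rgb=rgb_mean if name in RGB_VI else None)
            if not np.isfinite(v):
                n_missing += 1
                v = np.nan
            rec[name] = v
        rows.append(rec)
    if n_missing:
        log.warning("vi_table: %d undefined index values recorded as missing",
                    n_missing)
    return pd.DataFrame(rows)


def vi_map(cube: HyperspectralCube, name: str,
           rgb: RasterGrid | None = None) -> RasterGrid:
    """Per-pixel index image (map rendering only; tables use ROI means)."""
    if name in CUBE_VI:
        wls, fn = CUBE_VI[name]
        R = {w: cube.grid.values[band_at(cube, w)].astype(float) for w in wls}
        vals = fn(R)
    elif name in RGB_VI:
        if rgb is not None:
            scale = 255.0 if np.issubdtype(rgb.values.dtype, np.integer) else 1.0
            r, g, b = (rgb.values[i].astype(float) / scale for i in range(3))
        else:
            r, g, b = (cube.grid.values[band_at(cube, RGB_FALLBACK_NM[ch])]
                       .astype(float) for ch in "RGB")
        vals = RGB_VI[name](r, g, b)
    else:
        raise KeyError(f"unknown vegetation index {name!r}")
    return RasterGrid(values=np.asarray(vals, dtype=float),
                      transform=cube.grid.transform, nodata=None,
                      crs_id=cube.grid.crs_id)
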