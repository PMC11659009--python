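"""Canopy height model and plot-level structural metrics.

The canopy height model (CHM) is the per-pixel DSM minus DEM, with negative
differences (surface-reconstruction artifacts) clamped to zero and counted.
From the CHM and an excess-green/Otsu plant-vs-soil segmentation, five
structural metrics are derived per plot:

* PH, plant height (cm): mean CHM over plant pixels inside the plot.  Soil
  pixels are excluded so PH tracks the plants a field ruler would measure
  rather than being diluted by cover.
* PR, plant roughness (cm): interquartile range of plant-pixel CHM values.
* PC, plant cover: plant pixels / total plot pixels.
* PVM, plant volume metric (cm): PC x PH (a pixel-sum canopy volume in m^3
  is available as an optional extra column).
* CEFR, canopy elevation fluctuation rate:
  (mean - bottom-decile mean) / (top-decile mean - bottom-decile mean) of
  plant-pixel CHM values.  Decile *means* (not single percentiles) make the
  extremes robust to single-pixel spikes; a flat canopy (equal decile
  means) takes CEFR = 0 by convention, and an all-soil plot leaves CEFR
  missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from canopyagb.geo import PlotROI, RasterGrid, rasterize_roi

log = logging.getLogger(__name__)

__all__ = ["CanopyHeightModel", "chm", "plant_mask", "sf_record", "sf_table",
           "SF_COLUMNS"]

SF_COLUMNS = ("PH", "PR", "PC", "PVM", "CEFR")


@dataclass
class CanopyHeightModel:
    """Heights in meters above ground, everywhere >= 0."""

    grid: RasterGrid
    clamped_negative_count: int = 0


def chm(dsm: RasterGrid, dem: RasterGrid) -> CanopyHeightModel:
    """DSM - DEM per pixel; negatives clamped to zero and counted."""
    if dsm.shape != dem.shape or dsm.transform != dem.transform:
        raise ValueError("DSM and DEM must share shape and geotransform")
    diff = dsm.values.astype(float) - dem.values.astype(float)
    n_neg = int((diff < 0).sum())
    vals = np.maximum(diff, 0.0)
    return CanopyHeightModel(
        grid=RasterGrid(values=vals, transform=dsm.transform, crs_id=dsm.crs_id),
        clamped_negative_count=n_neg,
    )


def plant_mask(rgb: RasterGrid, method: str = "exg_otsu") -> np.ndarray:
    """Crop-vs-soil segmentation of an RGB orthomosaic.

    Excess green EXG = 2g - r - b on channels rescaled to [0, 1]; the
    threshold is Otsu's on a 256-bin EXG histogram, pixels above it are
    plant.  A single-valued EXG image has no threshold: everything is
    classified as soil, with a warning.
    """
    if method != "exg_otsu":
        raise ValueError(f"unknown segmentation method {method!r}")
    if rgb.values.ndim != 3 or rgb.values.shape[0] < 3:
        raise ValueError("plant_mask expects a 3-band RGB raster")
    scale = 255.0 if np.issubdtype(rgb.values.dtype, np.integer) else 1.0
    r, g, b = (rgb.values[i].astype(float) / scale for i in range(3))
    exg = 2.0 * g - r - b
    if np.ptp(exg) == 0:
        log.warning("plant_mask: constant excess-green image, returning all-soil")
        return np.zeros(exg.shape, dtype=bool)
    t = threshold_otsu(exg, nbins=256)
    return exg > t


def _decile_means(values: np.ndarray) -> tuple[float, float]:
    """Means of the lowest and highest decile (at least one value each)."""
    s = np.sort(values)
    k = max(1, int(np.ceil(s.size / 10)))
    return float(s[:k].mean()), float(s[-k:].mean())


def sf_record(chm_model: CanopyHeightModel, plant: np.ndarray, roi: np.ndarray,
              plot_id: str = "", extras: bool = False,
              pixel_area_m2: float | None = None) -> dict:
    """The five structural metrics for one plot ROI.

    ``extras`` adds PR_norm (IQR / median height) and, when ``pixel_area_m2``
    is given, PVM_sum_m3 (sum of plant-pixel heights x pixel area).
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError(f"plot {plot_id or '?'}: empty ROI")
    plant = np.asarray(plant, dtype=bool)
    sel = plant & roi
    rec: dict = {"plot_id": plot_id}
    pc = sel.sum() / roi.sum()
    if not sel.any():
        rec.update(PH=0.0, PR=0.0, PC=0.0, PVM=0.0, CEFR=np.nan)
        if extras:
            rec["PR_norm"] = np.nan
            if pixel_area_m2 is not None:
                rec["PVM_sum_m3"] = 0.0
        return rec
    h_cm = chm_model.grid.values[sel] * 100.0
    ph = float(h_cm.mean())
    q25, q75 = np.percentile(h_cm, [25, 75])
    lo, hi = _decile_means(h_cm)
    cefr = 0.0 if hi == lo else (ph - lo) / (hi - lo)
    rec.update(PH=ph, PR=float(q75 - q25), PC=float(pc), PVM=float(pc * ph),
               CEFR=float(cefr))
    if extras:
        med = float(np.median(h_cm))
        rec["PR_norm"] = (q75 - q25) / med if med > 0 else np.nan
        if pixel_area_m2 is not None:
            rec["PVM_sum_m3"] = float((h_cm / 100.0).sum() * pixel_area_m2)
    return rec


def sf_table(chm_model: CanopyHeightModel, rgb: RasterGrid,
             plots: list[PlotROI], extras: bool = False) -> pd.DataFrame:
    """One row of PH/PR/PC/PVM/CEFR per plot."""
    plant = plant_mask(rgb)
    t = chm_model.grid.transform
    px_area = abs(t.a * t.e - t.b * t.d)
    rows = []
    for roi in plots:
        mask = rasterize_roi(roi, chm_model.grid)
        rec = sf_record(chm_model, plant, mask, plot_id=roi.plot_id,
                        extras=extras, pixel_area_m2=px_area if extras else None)
        rec["stage"] = roi.stage
        rows.append(rec)
    df = pd.DataFrame(rows)
    cols = ["plot_id", "stage", *SF_COLUMNS]
    extra_cols = [c for c in df.columns if c not in cols]
    return df[cols + extra_cols]
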