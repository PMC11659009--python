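"""Synthetic field-scene generator.

Emulates a randomized-block nitrogen-rate trial on winter rapeseed: two
varieties x five nitrogen levels (0-360 kg N/ha) x three replicate blocks,
imaged at three growth stages (seedling, bolting, early blossoming).  For a
chosen stage it renders co-registered products on a common 2.5 cm grid:

* a hyperspectral reflectance cube (400-1000 nm, 150 bands) in which each
  pixel is a soil/vegetation linear mixture; the vegetation endmember's NIR
  plateau rises with plot biomass,
* an 8-bit RGB orthomosaic rendered from the cube's 650/550/450 nm bands,
* DEM (smooth bare ground) and DSM (ground + canopy height) rasters in
  meters, with DSM >= DEM everywhere by construction,
* plot polygons with treatment attributes, and a ground-truth table of
  per-plot AGB (kg/ha), plant height (cm) and cover fraction.

Per plot, AGB is lognormal around a stage- and N-level-specific mean (means
strictly increase with N level); height follows a power-law allometry
PH = a * AGB**b; cover follows a logistic link in AGB.  The canopy is a set
of blobs obtained by thresholding a smoothed Gaussian random field at the
cover quantile, so fractional cover is controlled exactly (up to pixel
rounding) while leaving the texture modules a spatially structured signal.

Identical seeds give bit-identical scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import box as shapely_box

from canopyagb.geo import Affine, HyperspectralCube, PlotROI, RasterGrid, STAGES

__all__ = ["SceneConfig", "Scene", "STAGE_PRESETS", "generate_scene", "truth_summary"]


# Stage presets: mean AGB per nitrogen level (kg/ha) and the cover logistic.
# The AGB gradient spans roughly 150-6000 kg/ha across the three stages, the
# range reported for destructive samples in comparable rapeseed trials; the
# common allometry PH = 0.25 * AGB**0.69 puts heights in the 8-110 cm range.
STAGE_PRESETS: dict[str, dict] = {
    "seedling": {
        "agb_base_kg_ha": (250.0, 400.0, 550.0, 700.0, 850.0),
        "cover_logistic": (0.004, 550.0),
    },
    "bolting": {
        "agb_base_kg_ha": (500.0, 800.0, 1100.0, 1400.0, 1700.0),
        "cover_logistic": (0.0022, 900.0),
    },
    "early_blossoming": {
        "agb_base_kg_ha": (1500.0, 2400.0, 3300.0, 4200.0, 5100.0),
        "cover_logistic": (0.0013, 1400.0),
    },
}

HEIGHT_ALLOMETRY = (0.25, 0.69)  # PH_cm = a * AGB_kg_ha ** b


@dataclass
class SceneConfig:
    """Parameters of one synthetic acquisition (one stage).

    ``agb_base_kg_ha``, ``height_allometry`` and ``cover_logistic`` default
    to the stage preset when left ``None``.  ``agb_cv`` is the lognormal
    coefficient of variation of plot AGB around its treatment mean.
    ``nir_gain`` couples the vegetation NIR plateau to AGB:
    plateau *= 1 + nir_gain * AGB / max(agb_base).
    """

    n_varieties: int = 2
    n_levels: int = 5
    replicates: int = 3
    plot_px: tuple[int, int] = (24, 24)
    gsd_m: float = 0.025
    stage: str = "bolting"
    agb_base_kg_ha: Sequence[float] | None = None
    agb_cv: float = 0.25
    height_allometry: tuple[float, float] | None = None
    cover_logistic: tuple[float, float] | None = None
    soil_spectrum: np.ndarray | None = None
    veg_spectrum: np.ndarray | None = None
    nir_gain: float = 0.3
    # plot-level nuisance variability, decoupled from AGB: soil brightness,
    # endmember jitter, allometric scatter and cover scatter.  Defaults put
    # realized feature-AGB correlations in the 0.6-0.9 range typical of
    # field campaigns rather than at an unrealistic ceiling.
    soil_brightness_cv: float = 0.06
    veg_jitter_cv: float = 0.06
    ph_cv: float = 0.25
    cover_logit_sd: float = 0.30
    noise_sd_reflectance: float = 0.01
    noise_sd_height: float = 0.02
    n_bands: int = 150
    wavelength_range_nm: tuple[float, float] = (400.0, 1000.0)
    gap_px: int = 4
    border_px: int = 8
    blob_sigma_px: float = 2.5
    mix_sigma_px: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.plot_px[0] <= 0 or self.plot_px[1] <= 0:
            raise ValueError("plot dimensions must be positive")
        disp = (self.agb_cv, self.noise_sd_reflectance, self.noise_sd_height,
                self.soil_brightness_cv, self.veg_jitter_cv, self.ph_cv,
                self.cover_logit_sd)
        if any(d < 0 for d in disp):
            raise ValueError("dispersions must be non-negative")
        preset = STAGE_PRESETS[self.stage]
        if self.agb_base_kg_ha is None:
            base = preset["agb_base_kg_ha"]
            if self.n_levels != len(base):
                # interpolate the preset gradient onto the requested level count
                base = tuple(np.interp(np.linspace(0, len(base) - 1, self.n_levels),
                                       np.arange(len(base)), base))
            self.agb_base_kg_ha = base
        self.agb_base_kg_ha = tuple(float(v) for v in self.agb_base_kg_ha)
        if len(self.agb_base_kg_ha) != self.n_levels:
            raise ValueError("agb_base_kg_ha must have one entry per n_level")
        if np.any(np.diff(self.agb_base_kg_ha) <= 0):
            raise ValueError("agb_base_kg_ha must strictly increase with n_level")
        if self.height_allometry is None:
            self.height_allometry = HEIGHT_ALLOMETRY
        if self.cover_logistic is None:
            self.cover_logistic = preset["cover_logistic"]


@dataclass
class Scene:
    """One generated acquisition: rasters, plots, and ground truth."""

    cube: HyperspectralCube
    rgb: RasterGrid
    dsm: RasterGrid
    dem: RasterGrid
    plots: list[PlotROI]
    truth: pd.DataFrame          # plot_id, agb_kg_ha, ph_cm, cover_frac
    observations: pd.DataFrame   # plot_id, stage, agb_kg_ha, ph_cm
    config: SceneConfig = field(repr=False, default=None)


def default_soil_spectrum(wl: np.ndarray) -> np.ndarray:
    """Dry loam: reflectance rising gently from blue to NIR."""
    return 0.10 + 0.20 * (wl - 400.0) / 600.0


def default_veg_spectrum(wl: np.ndarray, nir_plateau: float = 0.38) -> np.ndarray:
    """Green canopy: chlorophyll absorption, green bump, red edge, NIR plateau."""
    vis = 0.03 + 0.07 * np.exp(-(((wl - 550.0) / 35.0) ** 2))
    edge = 1.0 / (1.0 + np.exp(-(wl - 717.0) / 12.0))
    return vis + (nir_plateau - vis) * edge


def _cv_sigma(cv: float) -> float:
    """Lognormal sigma giving a mean-1 distribution with the requested CV."""
    return float(np.sqrt(np.log1p(cv ** 2)))


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    f = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(f, sigma, mode="reflect")
    s = f.std()
    return f / s if s > 0 else f


def generate_scene(config: SceneConfig) -> Scene:
    """Render a complete synthetic acquisition for ``config.stage``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    pr, pc_ = cfg.plot_px
    n_plots_block = cfg.n_levels * cfg.n_varieties

    # --- layout: replicate blocks side by side, levels x varieties inside ---
    block_rows = cfg.n_levels * pr + (cfg.n_levels - 1) * cfg.gap_px
    block_cols = cfg.n_varieties * pc_ + (cfg.n_varieties - 1) * cfg.gap_px
    rows = 2 * cfg.border_px + block_rows
    cols = (2 * cfg.border_px + cfg.replicates * block_cols
            + (cfg.replicates - 1) * 2 * cfg.gap_px)
    gsd = cfg.gsd_m
    transform = Affine(a=gsd, b=0.0, c=0.0, d=0.0, e=-gsd, f=rows * gsd)
    crs_id = "local-meters"

    wl = np.linspace(*cfg.wavelength_range_nm, cfg.n_bands)
    soil = (np.asarray(cfg.soil_spectrum, float) if cfg.soil_spectrum is not None
            else default_soil_spectrum(wl))
    veg0 = (np.asarray(cfg.veg_spectrum, float) if cfg.veg_spectrum is not None
            else default_veg_spectrum(wl))
    if np.allclose(soil, veg0):
        raise ValueError("degenerate spectra: soil and vegetation templates identical")

    a_h, b_h = cfg.height_allometry
    k_c, agb50 = cfg.cover_logistic
    agb_max = max(cfg.agb_base_kg_ha)
    sigma_ln = np.sqrt(np.log1p(cfg.agb_cv ** 2))

    # --- per-plot treatment assignment (randomized within each block) -------
    cells = [(v, l) for l in range(cfg.n_levels) for v in range(cfg.n_varieties)]
    records, rois, plot_regions = [], [], []
    for rep in range(1, cfg.replicates + 1):
        perm = rng.permutation(n_plots_block)
        block_c0 = cfg.border_px + (rep - 1) * (block_cols + 2 * cfg.gap_px)
        for pos, cell_idx in enumerate(perm):
            v, lvl = cells[cell_idx]
            li, vi = divmod(pos, cfg.n_varieties)
            r0 = cfg.border_px + li * (pr + cfg.gap_px)
            c0 = block_c0 + vi * (pc_ + cfg.gap_px)
            plot_id = f"C{v + 1}-N{lvl}-R{rep}"
            agb = float(np.exp(rng.normal(np.log(cfg.agb_base_kg_ha[lvl])
                                          - 0.5 * sigma_ln ** 2, sigma_ln)))
            # allometry times lognormal scatter; cover from a jittered logit
            ph_cm = a_h * agb ** b_h * float(np.exp(rng.normal(0.0, cfg.ph_cv)))
            logit = k_c * (agb - agb50) + rng.normal(0.0, cfg.cover_logit_sd)
            cover = 1.0 / (1.0 + np.exp(-logit))
            jit = {name: float(np.exp(rng.normal(-0.5 * s ** 2, s)))
                   for name, s in (("soil_scale", _cv_sigma(cfg.soil_brightness_cv)),
                                   ("veg_vis_scale", _cv_sigma(cfg.veg_jitter_cv)),
                                   ("veg_nir_scale", _cv_sigma(cfg.veg_jitter_cv)))}
            records.append({"plot_id": plot_id, "variety": f"C{v + 1}",
                            "n_level": f"N{lvl}", "replicate": rep,
                            "agb_kg_ha": agb, "ph_cm": ph_cm, "cover_frac": cover,
                            **jit})
            x0, y1 = transform.xy(c0, r0)
            x1, y0 = transform.xy(c0 + pc_, r0 + pr)
            rois.append(PlotROI(plot_id=plot_id, polygon=shapely_box(x0, y0, x1, y1),
                                variety=f"C{v + 1}", n_level=f"N{lvl}",
                                replicate=rep, stage=cfg.stage, crs_id=crs_id))
            plot_regions.append((slice(r0, r0 + pr), slice(c0, c0 + pc_)))

    truth = pd.DataFrame(records)

    # --- terrain -----------------------------------------------------------
    dem_vals = 20.0 + 0.05 * _smooth_field(rng, (rows, cols), sigma=25.0)
    canopy = np.zeros((rows, cols))
    plant = np.zeros((rows, cols), dtype=bool)
    nir_scale_map = np.ones((rows, cols))
    vis_scale_map = np.ones((rows, cols))
    soil_scale_map = np.ones((rows, cols))

    for rec, (rs, cs) in zip(records, plot_regions):
        # plant blobs: threshold a smoothed field at the cover quantile so the
        # realized cover equals the logistic target up to pixel rounding
        f = _smooth_field(rng, (pr, pc_), cfg.blob_sigma_px)
        n_pix = pr * pc_
        n_plant = int(round(rec["cover_frac"] * n_pix))
        n_plant = min(max(n_plant, 1), n_pix - 1)
        thresh = np.sort(f, axis=None)[n_pix - n_plant - 1]
        pm = f > thresh
        plant[rs, cs] = pm
        # positive height field, normalized to mean 1 over plant pixels
        h = np.exp(0.35 * _smooth_field(rng, (pr, pc_), cfg.blob_sigma_px))
        h /= h[pm].mean()
        ch = np.where(pm, rec["ph_cm"] / 100.0 * h, 0.0)
        if cfg.noise_sd_height > 0:
            ch = ch + np.where(pm, rng.normal(0.0, cfg.noise_sd_height, (pr, pc_)), 0.0)
        canopy[rs, cs] = np.maximum(ch, 0.0)
        nir_scale_map[rs, cs] = ((1.0 + cfg.nir_gain * rec["agb_kg_ha"] / agb_max)
                                 * rec["veg_nir_scale"])
        vis_scale_map[rs, cs] = rec["veg_vis_scale"]
        soil_scale_map[rs, cs] = rec["soil_scale"]

    dsm_vals = dem_vals + canopy

    # --- reflectance mixture ------------------------------------------------
    veg_weight = ndimage.gaussian_filter(plant.astype(float), cfg.mix_sigma_px,
                                         mode="reflect").clip(0.0, 1.0)
    # NIR scaling (AGB coupling x jitter) applies above the red edge only;
    # the visible part of the endmember carries its own plot-level jitter
    nir_sel = (wl >= 720.0).astype(float)[:, None, None]
    m = veg_weight[None, :, :]
    veg_px = veg0[:, None, None] * (vis_scale_map[None, :, :] * (1.0 - nir_sel)
                                    + nir_scale_map[None, :, :] * nir_sel)
    refl = m * veg_px + (1.0 - m) * soil[:, None, None] * soil_scale_map[None, :, :]
    if cfg.noise_sd_reflectance > 0:
        refl = refl + rng.normal(0.0, cfg.noise_sd_reflectance, refl.shape)
    refl = refl.clip(0.0, 1.5)

    cube = HyperspectralCube(
        grid=RasterGrid(values=refl, transform=transform, crs_id=crs_id),
        wavelengths_nm=wl,
    )

    # --- RGB render from the 650/550/450 nm bands ---------------------------
    rgb_bands = [int(np.argmin(np.abs(wl - t))) for t in (650.0, 550.0, 450.0)]
    rgb_vals = np.round(255.0 * refl[rgb_bands].clip(0.0, 1.0)).astype(np.uint8)
    rgb = RasterGrid(values=rgb_vals, transform=transform, crs_id=crs_id)

    dem = RasterGrid(values=dem_vals, transform=transform, crs_id=crs_id)
    dsm = RasterGrid(values=dsm_vals, transform=transform, crs_id=crs_id)

    obs = truth[["plot_id", "agb_kg_ha", "ph_cm"]].copy()
    obs.insert(1, "stage", cfg.stage)
    return Scene(cube=cube, rgb=rgb, dsm=dsm, dem=dem, plots=rois,
                 truth=truth, observations=obs, config=cfg)


def generate_multistage(config: SceneConfig, stages: Sequence[str] = STAGES,
                        ) -> dict[str, Scene]:
    """One scene per growth stage, with stage-specific presets.

    Each stage uses a seed derived from ``config.seed`` so acquisitions are
    independent draws; plot ids repeat across stages as in a real campaign.
    """
    out = {}
    for i, stage in enumerate(stages):
        cfg = replace(config, stage=stage, agb_base_kg_ha=None,
                      cover_logistic=None, seed=(config.seed * 1009 + i) % (2 ** 31))
        out[stage] = generate_scene(cfg)
    return out


def truth_summary(truth: pd.DataFrame, column: str = "agb_kg_ha") -> dict:
    """Min / mean / max / sample sd / CV% of a ground-truth column."""
    x = np.asarray(truth[column], dtype=float)
    if x.size < 2:
        raise ValueError("truth summary requires at least 2 plots")
    sd = float(np.std(x, ddof=1))
    mean = float(np.mean(x))
    return {"min": float(np.min(x)), "mean": mean, "max": float(np.max(x)),
            "sd": sd, "cv_pct": 100.0 * sd / mean}
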