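"""Windowed texture metrics from gray-level co-occurrence statistics.

Three metrics are produced per RGB band: Data Range (DR, the first-order
max-minus-min of the window), Variance (VAR) and Entropy (ENT), the latter
two computed from the window's gray-level co-occurrence matrix (GLCM).
Each pixel's value is the plain average over two window sizes (3x3, 5x5)
and four offset directions (0, 45, 90, 135 degrees); DR, being a
first-order statistic, averages over the window sizes only.

Conventions: co-occurrence at offset distance 1, accumulated symmetrically
(each pair counted in both orders) and normalized to sum 1; input bands are
linearly quantized to 32 gray levels before pairing; entropy uses the
natural logarithm (any base rescales ENT by a constant, immaterial after
correlation screening); borders are handled by edge-replicate padding so
the texture map keeps the input shape and zonal means stay unbiased near
plot edges.

DR is deliberately a first-order (occurrence) statistic: "data range" has
no co-occurrence definition; VAR and ENT also have first-order variants
available via ``order="occurrence"`` for tools that compute them that way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from canopyagb.geo import PlotROI, RasterGrid, rasterize_roi

__all__ = [
    "TextureConfig",
    "DIRECTION_OFFSETS",
    "quantize",
    "glcm",
    "texture_metric",
    "texture_map",
    "tf_table",
]

# pixel offsets (drow, dcol) per direction; symmetric accumulation makes the
# sign of the offset irrelevant
DIRECTION_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

METRICS = ("DR", "VAR", "ENT")
BAND_INDEX = {"R": 0, "G": 1, "B": 2}


@dataclass
class TextureConfig:
    window_sizes: tuple[int, ...] = (3, 5)
    directions_deg: tuple[int, ...] = (0, 45, 90, 135)
    gray_levels: int = 32
    metrics: tuple[str, ...] = METRICS
    bands: tuple[str, ...] = ("R", "G", "B")
    order: str = "cooccurrence"  # or "occurrence" for first-order VAR/ENT

    def __post_init__(self) -> None:
        for w in self.window_sizes:
            if w < 3 or w % 2 == 0:
                raise ValueError("window sizes must be odd and >= 3")
        if self.gray_levels < 2:
            raise ValueError("gray_levels must be >= 2")
        for d in self.directions_deg:
            if d not in DIRECTION_OFFSETS:
                raise ValueError(f"direction {d} not in {sorted(DIRECTION_OFFSETS)}")
        for m in self.metrics:
            if m not in METRICS:
                raise ValueError(f"unknown metric {m!r}")
        if self.order not in ("cooccurrence", "occurrence"):
            raise ValueError("order must be 'cooccurrence' or 'occurrence'")


def quantize(band: RasterGrid | np.ndarray, levels: int) -> np.ndarray:
    """Linear min-max binning of a band into integers 0..levels-1.

    The maximum value maps to levels-1; a constant band maps to all zeros.
    """
    vals = band.values if isinstance(band, RasterGrid) else np.asarray(band)
    vals = vals.astype(float)
    lo, hi = np.nanmin(vals), np.nanmax(vals)
    if not np.isfinite(lo) or hi == lo:
        return np.zeros(vals.shape, dtype=np.int64)
    q = np.floor((vals - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def _pairs(window: np.ndarray, direction_deg: int):
    """All (a, b) gray-level pairs at offset distance 1 inside the window."""
    dr, dc = DIRECTION_OFFSETS[direction_deg]
    h, w = window.shape
    r0, r1 = max(0, -dr), h - max(0, dr)
    c0, c1 = max(0, -dc), w - max(0, dc)
    if r1 <= r0 or c1 <= c0:
        return None
    a = window[r0:r1, c0:c1]
    b = window[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    return a.ravel(), b.ravel()


def glcm(window: np.ndarray, direction_deg: int, levels: int) -> np.ndarray:
    """Normalized symmetric co-occurrence matrix of one integer window."""
    window = np.asarray(window)
    if window.ndim != 2 or min(window.shape) < 1:
        raise ValueError("window must be a 2-D patch")
    pr = _pairs(window, direction_deg)
    if pr is None or pr[0].size == 0:
        raise ValueError("window too small: no valid pixel pairs at this offset")
    a, b = pr
    if a.max() >= levels or a.min() < 0 or b.max() >= levels or b.min() < 0:
        raise ValueError("window values outside [0, levels)")
    P = np.zeros((levels, levels), dtype=float)
    np.add.at(P, (a, b), 1.0)
    np.add.at(P, (b, a), 1.0)
    return P / P.sum()


def texture_metric(window: np.ndarray, metric: str, direction_deg: int = 0,
                   levels: int = 32, order: str = "cooccurrence") -> float:
    """One metric on one integer window.

    DR ignores the direction (first-order data range).  With
    ``order="occurrence"`` VAR/ENT are computed from the window's gray-level
    histogram instead of the GLCM.
    """
    window = np.asarray(window)
    if metric == "DR":
        return float(window.max() - window.min())
    if order == "occurrence":
        counts = np.bincount(window.ravel(), minlength=levels).astype(float)
        p = counts / counts.sum()
        if metric == "VAR":
            i = np.arange(levels)
            mu = (p * i).sum()
            return float((p * (i - mu) ** 2).sum())
        if metric == "ENT":
            nz = p[p > 0]
            return float(-(nz * np.log(nz)).sum())
    P = glcm(window, direction_deg, levels)
    i = np.arange(levels)[:, None]
    if metric == "VAR":
        mu = (P * i).sum()
        return float((P * (i - mu) ** 2).sum())
    if metric == "ENT":
        nz = P[P > 0]
        return float(-(nz * np.log(nz)).sum())
    raise ValueError(f"unknown metric {metric!r}")


def _sliding_codes(q: np.ndarray, w: int, direction_deg: int, levels: int):
    """Per-pixel symmetrized pair lists for every w x w window (edge-padded).

    Returns (first_elements, codes), both shaped (rows, cols, 2P) where P is
    the number of in-window pairs at the direction's offset.
    """
    p = w // 2
    padded = np.pad(q, p, mode="edge")
    sw = sliding_window_view(padded, (w, w))
    dr, dc = DIRECTION_OFFSETS[direction_deg]
    r0, r1 = max(0, -dr), w - max(0, dr)
    c0, c1 = max(0, -dc), w - max(0, dc)
    a = sw[:, :, r0:r1, c0:c1].reshape(*q.shape, -1)
    b = sw[:, :, r0 + dr:r1 + dr, c0 + dc:c1 + dc].reshape(*q.shape, -1)
    first = np.concatenate([a, b], axis=-1)
    codes = np.concatenate([a * levels + b, b * levels + a], axis=-1)
    return first, codes


def _map_var(first: np.ndarray) -> np.ndarray:
    # GLCM variance = variance of the first pair element under the
    # symmetrized empirical pair distribution
    return first.var(axis=-1)


def _map_ent(codes: np.ndarray) -> np.ndarray:
    # ENT = -sum_runs (c/K) ln(c/K) = ln K - mean(ln c_e) over elements,
    # where c_e is the multiplicity of each element's code in its window
    K = codes.shape[-1]
    S = np.sort(codes, axis=-1)
    idx = np.arange(K)
    starts = np.ones(S.shape, dtype=bool)
    starts[..., 1:] = S[..., 1:] != S[..., :-1]
    first_idx = np.maximum.accumulate(np.where(starts, idx, 0), axis=-1)
    is_last = np.ones(S.shape, dtype=bool)
    is_last[..., :-1] = starts[..., 1:]
    rev = np.where(is_last, idx, K - 1)[..., ::-1]
    last_idx = np.minimum.accumulate(rev, axis=-1)[..., ::-1]
    c = (last_idx - first_idx + 1).astype(float)
    return np.log(K) - np.log(c).mean(axis=-1)


def _map_occurrence(q: np.ndarray, w: int, levels: int, metric: str) -> np.ndarray:
    p = w // 2
    padded = np.pad(q, p, mode="edge")
    vals = sliding_window_view(padded, (w, w)).reshape(*q.shape, -1)
    if metric == "VAR":
        return vals.var(axis=-1)
    codes = np.sort(vals, axis=-1)
    return _map_ent_from_sorted_values(codes)


def _map_ent_from_sorted_values(S: np.ndarray) -> np.ndarray:
    K = S.shape[-1]
    idx = np.arange(K)
    starts = np.ones(S.shape, dtype=bool)
    starts[..., 1:] = S[..., 1:] != S[..., :-1]
    first_idx = np.maximum.accumulate(np.where(starts, idx, 0), axis=-1)
    is_last = np.ones(S.shape, dtype=bool)
    is_last[..., :-1] = starts[..., 1:]
    rev = np.where(is_last, idx, K - 1)[..., ::-1]
    last_idx = np.minimum.accumulate(rev, axis=-1)[..., ::-1]
    c = (last_idx - first_idx + 1).astype(float)
    return np.log(K) - np.log(c).mean(axis=-1)


def texture_map(band: RasterGrid | np.ndarray, cfg: TextureConfig,
                metric: str) -> RasterGrid:
    """Per-pixel texture metric averaged over window sizes and directions."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if isinstance(band, RasterGrid):
        transform, crs = band.transform, band.crs_id
        vals = band.values
    else:
        transform, crs = None, None
        vals = np.asarray(band)
    if vals.ndim != 2:
        raise ValueError("texture_map expects a single 2-D band")
    wmax = max(cfg.window_sizes)
    if min(vals.shape) < wmax:
        raise ValueError(f"band smaller than the largest window ({wmax})")
    q = quantize(vals, cfg.gray_levels)
    maps = []
    if metric == "DR":
        for w in cfg.window_sizes:
            mx = ndimage.maximum_filter(q, size=w, mode="nearest")
            mn = ndimage.minimum_filter(q, size=w, mode="nearest")
            maps.append((mx - mn).astype(float))
    elif cfg.order == "occurrence":
        for w in cfg.window_sizes:
            maps.append(_map_occurrence(q, w, cfg.gray_levels, metric))
    else:
        for w in cfg.window_sizes:
            for d in cfg.directions_deg:
                first, codes = _sliding_codes(q, w, d, cfg.gray_levels)
                maps.append(_map_var(first) if metric == "VAR" else _map_ent(codes))
    out = np.mean(maps, axis=0)
    if transform is None:
        return RasterGrid(values=out)
    return RasterGrid(values=out, transform=transform, crs_id=crs)


def tf_table(rgb: RasterGrid, plots: list[PlotROI],
             cfg: TextureConfig | None = None) -> pd.DataFrame:
    """Plot-mean texture metrics: columns RDR..BENT (3 metrics x 3 bands)."""
    cfg = cfg or TextureConfig()
    if rgb.values.ndim != 3 or rgb.values.shape[0] < 3:
        raise ValueError("tf_table expects a 3-band RGB raster")
    tmaps = {}
    for bname in cfg.bands:
        band = RasterGrid(values=rgb.values[BAND_INDEX[bname]],
                          transform=rgb.transform, crs_id=rgb.crs_id)
        for metric in cfg.metrics:
            tmaps[f"{bname}{metric}"] = texture_map(band, cfg, metric).values
    rows = []
    for roi in plots:
        mask = rasterize_roi(roi, rgb)
        rec = {"plot_id": roi.plot_id, "stage": roi.stage}
        for col, tmap in tmaps.items():
            rec[col] = float(tmap[mask].mean())
        rows.append(rec)
    return pd.DataFrame(rows)
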