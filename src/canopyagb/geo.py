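"""Raster and vector I/O plus the pixel-geometry services used by every stage.

Rasters are exchanged as GeoTIFFs written through :mod:`tifffile` with the
standard GeoTIFF georeferencing tags (ModelTransformation, GDAL nodata).
Hyperspectral cubes additionally carry an ENVI-style ``.hdr`` text sidecar
holding the per-band wavelength list, so a cube survives a write/read
round-trip with its spectral axis intact.

Map coordinates are treated as planar meters.  No reprojection is performed:
inputs must already share a CRS and a mismatch between declared CRS
identifiers is an error.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "Affine",
    "RasterGrid",
    "HyperspectralCube",
    "PlotROI",
    "GeoIOError",
    "read_raster",
    "write_raster",
    "band_at",
    "rasterize_roi",
    "read_plots",
    "read_observations",
]

STAGES = ("seedling", "bolting", "early_blossoming")

TAG_MODEL_PIXEL_SCALE = 33550
TAG_MODEL_TIEPOINT = 33922
TAG_MODEL_TRANSFORMATION = 34264
TAG_GDAL_NODATA = 42113


class GeoIOError(ValueError):
    """Raised for malformed rasters, headers, vectors or geometry mismatches."""


@dataclass(frozen=True)
class Affine:
    """Affine pixel->map transform, GDAL convention.

    ``x = c + a*col + b*row`` and ``y = f + d*col + e*row`` where (col, row)
    is measured from the upper-left corner of the upper-left pixel.
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    def __post_init__(self) -> None:
        if abs(self.a * self.e - self.b * self.d) < 1e-30:
            raise GeoIOError("geotransform is not invertible")

    def xy(self, col, row):
        """Map coordinates of a (fractional) pixel position."""
        return (self.c + self.a * col + self.b * row,
                self.f + self.d * col + self.e * row)

    def pixel_centers(self, rows: int, cols: int):
        """Map coordinates of every pixel center as (X, Y) arrays."""
        cc, rr = np.meshgrid(np.arange(cols) + 0.5, np.arange(rows) + 0.5)
        return self.xy(cc, rr)

    def to_gdal(self):
        return (self.c, self.a, self.b, self.f, self.d, self.e)


@dataclass
class RasterGrid:
    """A 2-D single-band or 3-D (bands, rows, cols) raster with georeference."""

    values: np.ndarray
    transform: Affine = field(default_factory=lambda: Affine(1, 0, 0, 0, -1, 0))
    nodata: float | None = None
    crs_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim not in (2, 3):
            raise GeoIOError("raster values must be 2-D or 3-D")
        if self.shape[0] < 1 or self.shape[1] < 1:
            raise GeoIOError("raster must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of the grid."""
        return self.values.shape[-2:]

    @property
    def n_bands(self) -> int:
        return 1 if self.values.ndim == 2 else self.values.shape[0]

    def valid_mask(self) -> np.ndarray:
        """True where a pixel holds data (finite and not the nodata sentinel)."""
        band0 = self.values if self.values.ndim == 2 else self.values[0]
        ok = np.isfinite(band0.astype(float))
        if self.nodata is not None:
            ok &= band0 != self.nodata
        return ok


@dataclass
class HyperspectralCube:
    """Wavelength-indexed reflectance raster (bands, rows, cols)."""

    grid: RasterGrid
    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.grid.values.ndim != 3:
            raise GeoIOError("hyperspectral cube requires a 3-D raster")
        if len(self.wavelengths_nm) != self.grid.values.shape[0]:
            raise GeoIOError(
                f"wavelength count {len(self.wavelengths_nm)} does not match "
                f"band count {self.grid.values.shape[0]}"
            )
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise GeoIOError("wavelengths must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


@dataclass
class PlotROI:
    """A field plot polygon with its treatment attributes.

    ``n_level`` is the ordinal nitrogen treatment label (``N0``..``N4``),
    ``replicate`` the block number of the randomized block design.
    """

    plot_id: str
    polygon: BaseGeometry
    variety: str
    n_level: str
    replicate: int
    stage: str | None = None
    crs_id: str | None = None

    def __post_init__(self) -> None:
        if not self.polygon.is_valid or self.polygon.area <= 0:
            raise GeoIOError(f"plot {self.plot_id}: polygon invalid or degenerate")
        if int(self.replicate) not in (1, 2, 3):
            raise GeoIOError(f"plot {self.plot_id}: replicate must be 1, 2 or 3")
        self.replicate = int(self.replicate)
        if self.stage is not None and self.stage not in STAGES:
            raise GeoIOError(f"plot {self.plot_id}: unknown stage {self.stage!r}")


# ---------------------------------------------------------------------------
# raster I/O


def _hdr_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".hdr")


def _write_envi_header(path: Path, grid: RasterGrid,
                       wavelengths: np.ndarray | None) -> None:
    rows, cols = grid.shape
    lines = [
        "ENVI",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {grid.n_bands}",
    ]
    if grid.nodata is not None:
        lines.append(f"data ignore value = {grid.nodata!r}")
    if wavelengths is not None:
        lines.append("wavelength units = Nanometers")
        wl = ", ".join(f"{w:.6g}" for w in wavelengths)
        lines.append("wavelength = { " + wl + " }")
    path.write_text("\n".join(lines) + "\n")


def _parse_envi_header(path: Path) -> dict:
    text = path.read_text()
    out: dict = {}
    m = re.search(r"wavelength\s*=\s*\{([^}]*)\}", text, flags=re.S)
    if m:
        out["wavelengths"] = np.array(
            [float(t) for t in m.group(1).replace("\n", " ").split(",") if t.strip()]
        )
    m = re.search(r"data ignore value\s*=\s*([-\d.eE+]+)", text)
    if m:
        out["nodata"] = float(m.group(1))
    return out


def write_raster(obj: RasterGrid | HyperspectralCube, path) -> Path:
    """Write a grid or cube to a GeoTIFF (+ ENVI ``.hdr`` sidecar for cubes).

    Round-trip through :func:`read_raster` is bitwise for integer rasters and
    exact at the stored dtype for floats.
    """
    path = Path(path)
    wavelengths = None
    if isinstance(obj, HyperspectralCube):
        wavelengths = obj.wavelengths_nm
        grid = obj.grid
    else:
        grid = obj
    t = grid.transform
    # row-major 4x4 ModelTransformation (z row and column zeroed)
    model = (t.a, t.b, 0.0, t.c,
             t.d, t.e, 0.0, t.f,
             0.0, 0.0, 0.0, 0.0,
             0.0, 0.0, 0.0, 1.0)
    extratags = [(TAG_MODEL_TRANSFORMATION, "d", 16, model, True)]
    if grid.nodata is not None:
        extratags.append((TAG_GDAL_NODATA, "s", 0, repr(float(grid.nodata)), True))
    descr = json.dumps({"crs_id": grid.crs_id})
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        tifffile.imwrite(path, grid.values, photometric="minisblack",
                         description=descr, extratags=extratags)
    except (OSError, PermissionError) as exc:
        raise GeoIOError(f"cannot write raster to {path}: {exc}") from exc
    if wavelengths is not None or grid.nodata is not None:
        _write_envi_header(_hdr_path(path), grid, wavelengths)
    return path


def read_raster(path) -> RasterGrid | HyperspectralCube:
    """Read a GeoTIFF; returns a cube iff per-band wavelengths are recoverable.

    Wavelengths come from an accompanying ENVI-style header
    (``<name>.tif.hdr``); a header whose wavelength count disagrees with the
    file's band count is an error rather than a silent truncation.
    """
    path = Path(path)
    if not path.exists():
        raise GeoIOError(f"raster file not found: {path}")
    with tifffile.TiffFile(path) as tf:
        values = tf.asarray()
        page = tf.pages[0]
        tags = page.tags
        transform = Affine(1, 0, 0, 0, -1, 0)
        if TAG_MODEL_TRANSFORMATION in tags:
            m = tags[TAG_MODEL_TRANSFORMATION].value
            transform = Affine(a=m[0], b=m[1], c=m[3], d=m[4], e=m[5], f=m[7])
        elif TAG_MODEL_PIXEL_SCALE in tags and TAG_MODEL_TIEPOINT in tags:
            sx, sy = tags[TAG_MODEL_PIXEL_SCALE].value[:2]
            tp = tags[TAG_MODEL_TIEPOINT].value
            transform = Affine(a=sx, b=0.0, c=tp[3] - sx * tp[0],
                               d=0.0, e=-sy, f=tp[4] + sy * tp[1])
        nodata = None
        if TAG_GDAL_NODATA in tags:
            nodata = float(str(tags[TAG_GDAL_NODATA].value).strip().strip("'\""))
        crs_id = None
        if page.description:
            try:
                crs_id = json.loads(page.description).get("crs_id")
            except (json.JSONDecodeError, AttributeError):
                pass
    grid = RasterGrid(values=values, transform=transform, nodata=nodata, crs_id=crs_id)
    hdr = _hdr_path(path)
    if hdr.exists():
        meta = _parse_envi_header(hdr)
        if grid.nodata is None and "nodata" in meta:
            grid.nodata = meta["nodata"]
        if "wavelengths" in meta:
            return HyperspectralCube(grid=grid, wavelengths_nm=meta["wavelengths"])
    return grid


# ---------------------------------------------------------------------------
# wavelength lookup


def band_at(cube: HyperspectralCube | Sequence[float], wavelength_nm: float) -> int:
    """Index of the band whose center wavelength is nearest the request.

    Ties resolve to the lower index.  A request farther from its nearest band
    than 1.5x the median band spacing is refused: on a 2.2 nm grid every
    common vegetation-index center resolves, while a sparse multispectral
    stack cannot be silently misused for a band it does not carry.
    """
    wl = np.asarray(
        cube.wavelengths_nm if isinstance(cube, HyperspectralCube) else cube,
        dtype=float,
    )
    if wl.size < 1:
        raise GeoIOError("empty wavelength list")
    dist = np.abs(wl - float(wavelength_nm))
    idx = int(np.argmin(dist))  # argmin takes the first (lower) index on ties
    spacing = float(np.median(np.diff(wl))) if wl.size > 1 else np.inf
    if dist[idx] > 1.5 * spacing:
        raise GeoIOError(
            f"no band within tolerance of {wavelength_nm} nm "
            f"(nearest {wl[idx]:.1f} nm, tolerance {1.5 * spacing:.2f} nm)"
        )
    return idx


# ---------------------------------------------------------------------------
# rasterization


def rasterize_roi(roi: PlotROI, grid: RasterGrid | HyperspectralCube) -> np.ndarray:
    """Boolean mask of pixels whose *center* falls inside the plot polygon.

    The pixel-center rule (rather than all-touched) keeps zonal means
    unbiased and the result independent of traversal order.  Masks of
    disjoint polygons are therefore disjoint.
    """
    if isinstance(grid, HyperspectralCube):
        grid = grid.grid
    if roi.crs_id is not None and grid.crs_id is not None and roi.crs_id != grid.crs_id:
        raise GeoIOError(
            f"plot {roi.plot_id}: CRS {roi.crs_id!r} does not match raster {grid.crs_id!r}"
        )
    rows, cols = grid.shape
    X, Y = grid.transform.pixel_centers(rows, cols)
    mask = np.zeros((rows, cols), dtype=bool)
    # limit the point-in-polygon test to the polygon's bounding box
    minx, miny, maxx, maxy = roi.polygon.bounds
    box = (X >= minx) & (X <= maxx) & (Y >= miny) & (Y <= maxy)
    if box.any():
        mask[box] = shapely.contains_xy(roi.polygon, X[box], Y[box])
    if not mask.any():
        raise GeoIOError(f"plot {roi.plot_id} does not overlap the raster extent")
    return mask


# ---------------------------------------------------------------------------
# vector / tabular I/O

_REQUIRED_PLOT_PROPS = ("plot_id", "variety", "n_level", "replicate")


def read_plots(path) -> list[PlotROI]:
    """Read plot polygons + treatment attributes from a GeoJSON FeatureCollection."""
    path = Path(path)
    if not path.exists():
        raise GeoIOError(f"plot file not found: {path}")
    doc = json.loads(path.read_text())
    features = doc.get("features", [])
    if not features:
        raise GeoIOError(f"{path}: empty feature collection")
    crs_id = None
    if isinstance(doc.get("crs"), dict):
        crs_id = doc["crs"].get("properties", {}).get("name")
    rois = []
    for feat in features:
        props = feat.get("properties") or {}
        missing = [k for k in _REQUIRED_PLOT_PROPS if k not in props]
        if missing:
            raise GeoIOError(f"{path}: feature missing attributes {missing}")
        rois.append(
            PlotROI(
                plot_id=str(props["plot_id"]),
                polygon=shapely_shape(feat["geometry"]),
                variety=str(props["variety"]),
                n_level=str(props["n_level"]),
                replicate=int(props["replicate"]),
                stage=props.get("stage"),
                crs_id=crs_id,
            )
        )
    ids = [r.plot_id for r in rois]
    if len(set(ids)) != len(ids):
        raise GeoIOError(f"{path}: duplicate plot_id values")
    return rois


def plots_to_geojson(rois: list[PlotROI], path) -> Path:
    """Write plots back to GeoJSON (inverse of :func:`read_plots`)."""
    feats = []
    for r in rois:
        props = {"plot_id": r.plot_id, "variety": r.variety,
                 "n_level": r.n_level, "replicate": r.replicate}
        if r.stage is not None:
            props["stage"] = r.stage
        feats.append({"type": "Feature", "properties": props,
                      "geometry": json.loads(shapely.to_geojson(r.polygon))})
    doc: dict = {"type": "FeatureCollection", "features": feats}
    crs_ids = {r.crs_id for r in rois if r.crs_id}
    if len(crs_ids) == 1:
        doc["crs"] = {"type": "name", "properties": {"name": crs_ids.pop()}}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc))
    return path


OBS_COLUMNS = ("plot_id", "stage", "agb_kg_ha", "ph_cm")


def read_observations(path) -> pd.DataFrame:
    """Read the per-plot observed AGB (kg/ha) and plant height (cm) table.

    The key (plot_id, stage) must be unique.
    """
    path = Path(path)
    if not path.exists():
        raise GeoIOError(f"observation file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise GeoIOError(f"{path}: missing columns {missing}")
    if df.empty:
        raise GeoIOError(f"{path}: no observation rows")
    dup = df.duplicated(subset=["plot_id", "stage"])
    if dup.any():
        keys = df.loc[dup, ["plot_id", "stage"]].to_records(index=False).tolist()
        raise GeoIOError(f"{path}: duplicate (plot_id, stage) keys {keys[:5]}")
    return df
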