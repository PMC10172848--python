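"""Per-deme predictor table: raster sampling, kernel density, convex hulls.

Environmental predictors enter the regression as the raster value at each
deme center (nearest-pixel lookup, matching the common GIS point-extraction
convention).  Sampling intensity enters as an unnormalized Gaussian kernel
density of the individuals' coordinates (bandwidth in great-circle km;
default 200 km) — tree ensembles are invariant to monotone rescaling of a
single predictor, so the kernel normalization constant is irrelevant.
Categorical occurrence data (e.g. language-family point locations) enter as
0/1 presence inside the union of k-nearest-neighbor local convex hulls
(k-LoCoH).

Raster formats: ESRI ASCII grid (hand-parsed; it is a 6-line-header text
format) and single-band GeoTIFF via tifffile (ModelPixelScale/ModelTiepoint
tags).  Rasters must be in geographic (lon/lat) coordinates.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import DemeLattice, GeoPoint, pairwise_great_circle_km

logger = logging.getLogger(__name__)

KERNEL_COLUMN = "kernel_density"
DEFAULT_BANDWIDTH_KM = 200.0
DEFAULT_LOCOH_K = 10

__all__ = [
    "RasterLayer",
    "HullSet",
    "KERNEL_COLUMN",
    "read_raster",
    "write_raster",
    "sample_at",
    "kernel_density",
    "locoh_hulls",
    "presence_at",
    "assemble_table",
    "read_points_tsv",
]


@dataclass
class RasterLayer:
    """Single-band raster: row-major values, top-left origin, pixel size in degrees."""

    name: str
    values: np.ndarray
    origin: GeoPoint          # top-left CORNER of the top-left pixel
    pixel_deg: tuple[float, float]  # (dx, dy), both positive
    nodata: float = float("nan")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("raster values must be a nonempty 2-D grid")
        dx, dy = self.pixel_deg
        if dx <= 0 or dy <= 0:
            raise ValueError("pixel sizes must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def read_raster(path, name: str | None = None) -> RasterLayer:
    """Read a single-band ESRI ASCII grid or GeoTIFF.

    The raster must be in a geographic (lon/lat) CRS; projected GeoTIFFs
    raise with advice to reproject.  Multi-band inputs are rejected.
    """
    name = name or os.path.splitext(os.path.basename(path))[0]
    lower = str(path).lower()
    if lower.endswith((".tif", ".tiff")):
        return _read_geotiff(path, name)
    return _read_ascii_grid(path, name)


def _read_ascii_grid(path, name: str) -> RasterLayer:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0][0].isalpha():
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: ESRI ASCII grid missing header field {key!r}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cell = header["cellsize"]
    values = np.array([v for row in rows for v in row]).reshape(nrows, ncols)
    if "xllcorner" in header:
        xll, yll = header["xllcorner"], header["yllcorner"]
    else:
        xll = header["xllcenter"] - cell / 2.0
        yll = header["yllcenter"] - cell / 2.0
    nodata = header.get("nodata_value", float("nan"))
    origin = GeoPoint(xll, yll + nrows * cell)
    return RasterLayer(name, values, origin, (cell, cell), nodata)


def _read_geotiff(path, name: str) -> RasterLayer:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        if values.ndim != 2:
            raise ValueError(f"{path}: multi-band rasters are not supported")
        tags = {t.name: t.value for t in page.tags.values()}
    scale = tags.get("ModelPixelScaleTag")
    tie = tags.get("ModelTiepointTag")
    if scale is None or tie is None:
        raise ValueError(f"{path}: GeoTIFF lacks geotransform tags")
    geokeys = tags.get("GeoKeyDirectoryTag")
    if geokeys is not None:
        gk = np.asarray(geokeys).ravel()
        for k in range(4, len(gk) - 3, 4):
            if gk[k] == 1024 and gk[k + 3] != 2:  # GTModelTypeGeoKey, 2 = geographic
                raise ValueError(
                    f"{path}: raster is in a projected CRS; reproject to "
                    "geographic lon/lat before use"
                )
    dx, dy = float(scale[0]), float(scale[1])
    # tiepoint: raster (i, j) -> model (x, y); standard case ties pixel (0, 0)
    i, j, _, x, y, _ = (float(v) for v in np.asarray(tie).ravel()[:6])
    origin = GeoPoint(x - i * dx, y + j * dy)
    nodata = float(tags["GDAL_NODATA"]) if "GDAL_NODATA" in tags else float("nan")
    return RasterLayer(name, values, origin, (dx, dy), nodata)


def write_raster(layer: RasterLayer, path) -> None:
    """Write an ESRI ASCII grid (requires square pixels)."""
    dx, dy = layer.pixel_deg
    if abs(dx - dy) > 1e-9 * max(dx, dy):
        raise ValueError("ESRI ASCII grids require square pixels")
    nrows, ncols = layer.shape
    nodata = layer.nodata if np.isfinite(layer.nodata) else -9999.0
    vals = np.where(np.isnan(layer.values), nodata, layer.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\nnrows {nrows}\n")
        fh.write(f"xllcorner {layer.origin.lon:.12g}\n")
        fh.write(f"yllcorner {layer.origin.lat - nrows * dy:.12g}\n")
        fh.write(f"cellsize {dx:.12g}\nNODATA_value {nodata:.12g}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.12g}" for v in row) + "\n")


def sample_at(raster: RasterLayer, points) -> np.ndarray:
    """Nearest-pixel raster values at points; NaN outside extent or on nodata."""
    lons = np.array([p.lon for p in points])
    lats = np.array([p.lat for p in points])
    dx, dy = raster.pixel_deg
    nrows, ncols = raster.shape
    fcol = (lons - raster.origin.lon) / dx
    frow = (raster.origin.lat - lats) / dy
    eps = 1e-9
    # points on the extreme right/bottom extent edge belong to the last pixel
    col = np.minimum(np.floor(fcol + eps), ncols - 1).astype(int)
    row = np.minimum(np.floor(frow + eps), nrows - 1).astype(int)
    out = np.full(len(lons), np.nan)
    ok = (fcol >= -eps) & (fcol <= ncols + eps) & (frow >= -eps) & (frow <= nrows + eps)
    out[ok] = raster.values[row[ok], col[ok]]
    if np.isfinite(raster.nodata):
        out[np.isclose(out, raster.nodata)] = np.nan
    return out


def kernel_density(sample_points, eval_points, bandwidth_km: float = DEFAULT_BANDWIDTH_KM) -> np.ndarray:
    """Unnormalized Gaussian kernel density of samples at evaluation points.

    density(e) = sum_i exp(-rho(e, i)^2 / (2 bw^2)) with rho the great-circle
    distance in km.
    """
    if bandwidth_km <= 0:
        raise ValueError("bandwidth_km must be positive")
    if len(sample_points) == 0:
        logger.warning("kernel_density: no sample points; returning zeros")
        return np.zeros(len(eval_points))
    slon = np.array([p.lon for p in sample_points])
    slat = np.array([p.lat for p in sample_points])
    elon = np.array([p.lon for p in eval_points])
    elat = np.array([p.lat for p in eval_points])
    d = pairwise_great_circle_km(
        elon[:, None], elat[:, None], slon[None, :], slat[None, :]
    )
    return np.exp(-(d ** 2) / (2.0 * bandwidth_km ** 2)).sum(axis=1)


@dataclass
class HullSet:
    """Named set of simple polygons (lon/lat); union taken at query time."""

    name: str
    polygons: list = field(default_factory=list)


def locoh_hulls(points, k: int = DEFAULT_LOCOH_K, name: str = "hulls") -> HullSet:
    """k-LoCoH: convex hull of each point with its k-1 nearest neighbors.

    Neighborhoods are by great-circle distance.  Degenerate (collinear)
    neighborhoods yield no polygon and are skipped with a log message.
    """
    from shapely.geometry import MultiPoint, Polygon

    if k < 3:
        raise ValueError("locoh k must be at least 3")
    if len(points) < k:
        raise ValueError(f"need at least k={k} points, got {len(points)}")
    lons = np.array([p.lon for p in points])
    lats = np.array([p.lat for p in points])
    d = pairwise_great_circle_km(
        lons[:, None], lats[:, None], lons[None, :], lats[None, :]
    )
    polygons = []
    skipped = 0
    for i in range(len(points)):
        nbrs = np.argsort(d[i], kind="stable")[:k]
        hull = MultiPoint([(lons[j], lats[j]) for j in nbrs]).convex_hull
        if isinstance(hull, Polygon) and hull.area > 0:
            polygons.append(hull)
        else:
            skipped += 1
    if skipped:
        logger.info("locoh_hulls: skipped %d degenerate (collinear) hulls", skipped)
    if not polygons:
        raise ValueError("all k-neighborhoods were collinear; no hulls produced")
    return HullSet(name, polygons)


def presence_at(hulls: HullSet, points) -> np.ndarray:
    """1 where a point lies inside or on the boundary of any hull, else 0."""
    from shapely.geometry import Point

    out = np.zeros(len(points), dtype=int)
    for i, p in enumerate(points):
        pt = Point(p.lon, p.lat)
        if any(poly.covers(pt) for poly in hulls.polygons):
            out[i] = 1
    return out


def assemble_table(
    lattice: DemeLattice,
    rasters=(),
    hull_sets=(),
    sample_points=(),
    include_kernel: bool = True,
    bandwidth_km: float = DEFAULT_BANDWIDTH_KM,
) -> pd.DataFrame:
    """One predictor row per habitable deme, indexed by deme_id.

    Column order is deterministic: rasters in input order, then hull
    presences, then the kernel density (when requested).  Demes with any
    missing raster value are dropped (count logged), never imputed.
    """
    hab = lattice.habitable_ids
    centers = [lattice.center(int(d)) for d in hab]
    cols: dict[str, np.ndarray] = {}
    for r in rasters:
        if r.name in cols:
            raise ValueError(f"duplicate predictor column name {r.name!r}")
        cols[r.name] = sample_at(r, centers)
    for hs in hull_sets:
        if hs.name in cols:
            raise ValueError(f"duplicate predictor column name {hs.name!r}")
        cols[hs.name] = presence_at(hs, centers).astype(float)
    if include_kernel:
        if KERNEL_COLUMN in cols:
            raise ValueError(f"duplicate predictor column name {KERNEL_COLUMN!r}")
        cols[KERNEL_COLUMN] = kernel_density(list(sample_points), centers, bandwidth_km)
    table = pd.DataFrame(cols, index=pd.Index(hab, name="deme_id"))
    n_before = len(table)
    table = table.dropna()
    dropped = n_before - len(table)
    if dropped:
        logger.info(
            "assemble_table: dropped %d demes with missing raster values", dropped
        )
    return table


def read_points_tsv(path) -> list[GeoPoint]:
    """Read a point table with columns name/id, lon, lat (header optional)."""
    pts = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            try:
                lon, lat = float(parts[-2]), float(parts[-1])
            except ValueError:
                continue  # header line
            pts.append(GeoPoint(lon, lat))
    return pts
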