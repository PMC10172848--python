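"""Geographic primitives: points, bounding boxes, and the triangular deme lattice.

Migration surfaces are estimated on a lattice of demes (local panmictic
subpopulations) with up to six neighbors each.  The lattice is constructed in
a plate-carrée approximation of the bounding box: longitudes are scaled by
``cos(mean latitude)`` so that, at the regional scales this package targets,
the construction plane is metric in kilometres.  All point-to-point distances
elsewhere use the haversine great-circle formula on a sphere of radius
6371.0 km.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

EARTH_RADIUS_KM = 6371.0
KM_PER_DEG = EARTH_RADIUS_KM * math.pi / 180.0  # ~111.195 km per degree of latitude

__all__ = [
    "EARTH_RADIUS_KM",
    "KM_PER_DEG",
    "GeoPoint",
    "BoundingBox",
    "DemeLattice",
    "build_lattice",
    "assign_individuals",
    "great_circle_km",
    "pairwise_great_circle_km",
    "great_circle_midpoint",
]


@dataclass(frozen=True)
class GeoPoint:
    """A WGS84 longitude/latitude pair in decimal degrees."""

    lon: float
    lat: float

    def __post_init__(self) -> None:
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned region given by its top-left and bottom-right corners."""

    top_left: GeoPoint
    bottom_right: GeoPoint

    def __post_init__(self) -> None:
        if self.top_left.lat <= self.bottom_right.lat:
            raise ValueError(
                "degenerate bounding box: top_left latitude "
                f"{self.top_left.lat} must exceed bottom_right latitude "
                f"{self.bottom_right.lat}"
            )
        if self.top_left.lon >= self.bottom_right.lon:
            raise ValueError(
                "degenerate bounding box: top_left longitude "
                f"{self.top_left.lon} must be west of bottom_right longitude "
                f"{self.bottom_right.lon}"
            )

    @property
    def mean_lat(self) -> float:
        return 0.5 * (self.top_left.lat + self.bottom_right.lat)

    @property
    def width_km(self) -> float:
        dlon = self.bottom_right.lon - self.top_left.lon
        return dlon * KM_PER_DEG * math.cos(math.radians(self.mean_lat))

    @property
    def height_km(self) -> float:
        return (self.top_left.lat - self.bottom_right.lat) * KM_PER_DEG

    def contains(self, p: GeoPoint) -> bool:
        return (
            self.top_left.lon <= p.lon <= self.bottom_right.lon
            and self.bottom_right.lat <= p.lat <= self.top_left.lat
        )


def great_circle_km(a: GeoPoint, b: GeoPoint) -> float:
    """Haversine distance between two points, in km."""
    return float(
        pairwise_great_circle_km(
            np.array([a.lon]), np.array([a.lat]), np.array([b.lon]), np.array([b.lat])
        )[0]
    )


def pairwise_great_circle_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Vectorized haversine distance; inputs broadcast elementwise (degrees)."""
    lon1, lat1 = np.radians(lon1), np.radians(lat1)
    lon2, lat2 = np.radians(lon2), np.radians(lat2)
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))


def great_circle_midpoint(a: GeoPoint, b: GeoPoint) -> GeoPoint:
    """Midpoint of the great-circle arc between two points (3-vector mean)."""
    v = _unit_vectors(np.array([a.lon, b.lon]), np.array([a.lat, b.lat]))
    m = v.mean(axis=0)
    n = np.linalg.norm(m)
    if n < 1e-12:  # antipodal points: midpoint undefined, pick a's meridian pole-ward
        return GeoPoint(a.lon, 0.0)
    m /= n
    lat = math.degrees(math.asin(np.clip(m[2], -1.0, 1.0)))
    lon = math.degrees(math.atan2(m[1], m[0]))
    return GeoPoint(lon, lat)


def _unit_vectors(lon_deg, lat_deg) -> np.ndarray:
    lon = np.radians(np.asarray(lon_deg, dtype=float))
    lat = np.radians(np.asarray(lat_deg, dtype=float))
    return np.stack(
        [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)], axis=-1
    )


@dataclass
class DemeLattice:
    """Equilateral-triangle lattice of demes with six-neighbor adjacency.

    Demes are numbered row-major from the top-left corner of the bounding
    box.  ``adjacency[d]`` is the sorted tuple of neighbor ids of deme ``d``;
    interior demes have exactly six neighbors.
    """

    lons: np.ndarray
    lats: np.ndarray
    adjacency: tuple[tuple[int, ...], ...]
    habitable: np.ndarray
    step_km: float
    bbox: BoundingBox
    n_rows: int = 0
    n_cols: int = 0
    # planar construction coordinates (km), kept for exact edge geometry
    xy_km: np.ndarray = field(default=None, repr=False)

    @property
    def n_demes(self) -> int:
        return len(self.lons)

    @property
    def deme_ids(self) -> np.ndarray:
        return np.arange(self.n_demes)

    @property
    def habitable_ids(self) -> np.ndarray:
        return np.flatnonzero(self.habitable)

    def center(self, d: int) -> GeoPoint:
        return GeoPoint(float(self.lons[d]), float(self.lats[d]))

    def edges(self):
        """Yield each undirected adjacency edge (i, j) once, i < j."""
        for i, nbrs in enumerate(self.adjacency):
            for j in nbrs:
                if j > i:
                    yield i, j

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("deme_id\tlon\tlat\thabitable\tneighbor_ids\n")
            for d in range(self.n_demes):
                nbrs = ";".join(str(j) for j in self.adjacency[d])
                fh.write(
                    f"{d}\t{self.lons[d]:.10g}\t{self.lats[d]:.10g}\t"
                    f"{int(self.habitable[d])}\t{nbrs}\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "DemeLattice":
        lons, lats, hab, adj = [], [], [], []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("deme_id"):
                raise ValueError(f"{path}: not a lattice TSV (bad header)")
            for line in fh:
                _, lon, lat, h, nbrs = line.rstrip("\n").split("\t")
                lons.append(float(lon))
                lats.append(float(lat))
                hab.append(bool(int(h)))
                adj.append(tuple(int(x) for x in nbrs.split(";")) if nbrs else ())
        lons = np.array(lons)
        lats = np.array(lats)
        bbox = BoundingBox(
            GeoPoint(float(lons.min()), float(lats.max()) + 1e-9),
            GeoPoint(float(lons.max()) + 1e-9, float(lats.min())),
        )
        step = _infer_step_km(lons, lats, adj)
        return cls(lons, lats, tuple(adj), np.array(hab), step, bbox)


def _infer_step_km(lons, lats, adj) -> float:
    d = []
    for i, nbrs in enumerate(adj):
        for j in nbrs:
            if j > i:
                d.append(
                    pairwise_great_circle_km(lons[i], lats[i], lons[j], lats[j])
                )
    return float(np.median(d)) if d else 1.0


def build_lattice(bbox: BoundingBox, target_demes: int, habitat_mask=None) -> DemeLattice:
    """Build a triangular deme lattice covering ``bbox``.

    The number of rows and columns is chosen so that rows*cols is as close
    as possible to ``target_demes`` while roughly matching the box's aspect
    ratio; the lattice is then laid out with a single equilateral step
    anchored at the top-left corner, so every adjacency edge has the same
    construction length.

    ``habitat_mask`` may be a shapely geometry, an iterable of shapely
    polygons, or a GeoJSON file path; demes whose centers fall outside it
    are flagged uninhabitable.
    """
    if target_demes < 4:
        raise ValueError("target_demes must be at least 4")
    W, H = bbox.width_km, bbox.height_km
    sh = math.sqrt(3.0) / 2.0

    # choose nrows x ncols ~ target with (ncols-0.5)/(nrows-1) ~ W/(H/sh)
    ncols0 = math.sqrt(max(target_demes * W * sh / H, 4.0))
    best = None
    nr_max = min(max(int(2 * math.sqrt(target_demes)) + 4, target_demes // 2 + 2), 5000)
    for nr in range(2, nr_max):
        nc = max(2, round(target_demes / nr))
        for nc_try in (nc - 1, nc, nc + 1):
            if nc_try < 2:
                continue
            count = nr * nc_try
            aspect_err = abs(nc_try - ncols0)
            key = (abs(count - target_demes), aspect_err, nr, nc_try)
            if best is None or key < best[0]:
                best = (key, nr, nc_try)
    _, n_rows, n_cols = best
    step = min(W / (n_cols - 0.5), H / ((n_rows - 1) * sh))

    cosref = math.cos(math.radians(bbox.mean_lat))
    lon0, lat0 = bbox.top_left.lon, bbox.top_left.lat
    lons, lats, xy = [], [], []
    for r in range(n_rows):
        y = r * step * sh
        xoff = 0.5 * step if r % 2 else 0.0
        for c in range(n_cols):
            x = xoff + c * step
            lons.append(lon0 + x / (KM_PER_DEG * cosref))
            lats.append(lat0 - y / KM_PER_DEG)
            xy.append((x, y))
    lons = np.array(lons)
    lats = np.array(lats)

    def did(r, c):
        return r * n_cols + c

    adjacency = []
    for r in range(n_rows):
        for c in range(n_cols):
            nbrs = []
            if c > 0:
                nbrs.append(did(r, c - 1))
            if c < n_cols - 1:
                nbrs.append(did(r, c + 1))
            offs = (c - 1, c) if r % 2 == 0 else (c, c + 1)
            for rr in (r - 1, r + 1):
                if 0 <= rr < n_rows:
                    for cc in offs:
                        if 0 <= cc < n_cols:
                            nbrs.append(did(rr, cc))
            adjacency.append(tuple(sorted(nbrs)))

    habitable = np.ones(len(lons), dtype=bool)
    if habitat_mask is not None:
        habitable = _apply_mask(habitat_mask, lons, lats)

    return DemeLattice(
        lons,
        lats,
        tuple(adjacency),
        habitable,
        float(step),
        bbox,
        n_rows,
        n_cols,
        np.array(xy),
    )


def _apply_mask(mask, lons, lats) -> np.ndarray:
    from shapely.geometry import Point, shape
    from shapely.geometry.base import BaseGeometry
    from shapely.ops import unary_union

    if isinstance(mask, (str, bytes)) or hasattr(mask, "read_text"):
        with open(mask) as fh:
            gj = json.load(fh)
        if gj.get("type") == "FeatureCollection":
            geoms = [shape(f["geometry"]) for f in gj["features"]]
        elif gj.get("type") == "Feature":
            geoms = [shape(gj["geometry"])]
        else:
            geoms = [shape(gj)]
        geom = unary_union(geoms)
    elif isinstance(mask, BaseGeometry):
        geom = mask
    else:
        geom = unary_union(list(mask))
    return np.array([geom.covers(Point(x, y)) for x, y in zip(lons, lats)])


def assign_individuals(lattice: DemeLattice, points: list[GeoPoint]) -> np.ndarray:
    """Map each point to the nearest habitable deme center (great-circle).

    Exact distance ties break to the lowest deme id.  Returns an int array
    of deme ids aligned with ``points``.
    """
    if lattice.n_demes == 0:
        raise ValueError("lattice has no demes")
    hab = lattice.habitable_ids
    if hab.size == 0:
        raise ValueError("lattice has no habitable demes; cannot assign individuals")
    if len(points) == 0:
        return np.empty(0, dtype=int)
    plons = np.array([p.lon for p in points])
    plats = np.array([p.lat for p in points])
    d = pairwise_great_circle_km(
        plons[:, None], plats[:, None], lattice.lons[hab][None, :], lattice.lats[hab][None, :]
    )
    return hab[np.argmin(d, axis=1)]
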