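"""Per-deme migration surfaces: MAPS output ingestion and transforms.

The effective-migration estimator we interoperate with writes a per-deme
migration rate ``m`` on a log10 scale (mRates.txt) and the deme coordinates
in estimation order (demes.txt).  This module converts those into
:class:`MigrationSurface` objects on our lattice, averages replicate runs on
the linear scale, derives the dispersal distance sigma = step * sqrt(m), and
produces the natural-log response vector used downstream by the regression
model (migration rates are strongly right-skewed, so the response is
log-transformed).

A kernel-smoothed heuristic surface (:func:`baseline_surface`) is provided
so that the full pipeline can be exercised without an external MCMC run.  It
is a smoke-test device, not an estimator of publication quality, and is
labelled as such in logs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geo import (
    DemeLattice,
    GeoPoint,
    great_circle_midpoint,
    pairwise_great_circle_km,
)
from .ibd import SharingMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MigrationSurface",
    "DispersalSurface",
    "ResponseVector",
    "read_maps_output",
    "write_maps_output",
    "average_replicates",
    "to_dispersal",
    "make_response",
    "baseline_surface",
]


@dataclass
class MigrationSurface:
    """Per-deme migration rates on log10 scale, defined on ``deme_ids``."""

    lattice: DemeLattice
    deme_ids: np.ndarray
    log10_m: np.ndarray
    source: str  # {"maps", "baseline", "synthetic"}

    def __post_init__(self) -> None:
        self.deme_ids = np.asarray(self.deme_ids, dtype=int)
        self.log10_m = np.asarray(self.log10_m, dtype=float)
        if self.deme_ids.shape != self.log10_m.shape:
            raise ValueError("deme_ids and log10_m must be aligned")
        if not np.all(np.isfinite(self.log10_m)):
            raise ValueError("log10_m contains non-finite values")

    @property
    def m_linear(self) -> np.ndarray:
        return 10.0 ** self.log10_m

    def to_tsv(self, path, step_km: float | None = None) -> None:
        sigma = to_dispersal(self, step_km or self.lattice.step_km).sigma_km
        y = np.log(self.m_linear)
        with open(path, "w") as fh:
            fh.write("deme_id\tlon\tlat\tlog10_m\tm_linear\tsigma_km\tresponse\n")
            for i, d in enumerate(self.deme_ids):
                fh.write(
                    f"{d}\t{self.lattice.lons[d]:.10g}\t{self.lattice.lats[d]:.10g}\t"
                    f"{self.log10_m[i]:.10g}\t{self.m_linear[i]:.10g}\t"
                    f"{sigma[i]:.10g}\t{y[i]:.10g}\n"
                )


@dataclass
class DispersalSurface:
    """Root-mean-square per-generation dispersal distance sigma, in km."""

    lattice: DemeLattice
    deme_ids: np.ndarray
    sigma_km: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.sigma_km) <= 0):
            raise ValueError("sigma_km must be strictly positive")


@dataclass
class ResponseVector:
    """Natural-log migration response over habitable demes."""

    deme_ids: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.deme_ids = np.asarray(self.deme_ids, dtype=int)
        self.y = np.asarray(self.y, dtype=float)
        if self.deme_ids.shape != self.y.shape:
            raise ValueError("deme_ids and y must be aligned")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("response contains non-finite values")


def plot_surface(surface: MigrationSurface, ax=None, **scatter_kw):
    """Debug scatter of the surface: deme centers colored by log10 rate."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    lons = surface.lattice.lons[surface.deme_ids]
    lats = surface.lattice.lats[surface.deme_ids]
    sc = ax.scatter(lons, lats, c=surface.log10_m, **scatter_kw)
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    ax.figure.colorbar(sc, ax=ax, label="log10 migration rate")
    return ax


def read_maps_output(mrates_path, demes_path, lattice: DemeLattice) -> MigrationSurface:
    """Read mRates.txt / demes.txt into a surface on ``lattice``.

    mRates.txt is read as whitespace-separated numeric tokens; a token count
    that is an integer multiple k > 1 of the deme count is interpreted as k
    posterior draws and averaged per deme (on the log10 scale, as stored).
    Deme rows (lon lat) are matched to lattice demes by nearest center.
    """
    tokens = np.loadtxt(mrates_path).ravel()
    coords = np.loadtxt(demes_path, ndmin=2)
    if coords.shape[1] != 2:
        raise ValueError(f"{demes_path}: expected 2 columns (lon lat)")
    n_demes = coords.shape[0]
    if tokens.size == 0 or tokens.size % n_demes != 0:
        raise ValueError(
            f"{mrates_path}: {tokens.size} rate tokens is not a multiple of "
            f"{n_demes} deme rows in {demes_path}"
        )
    draws = tokens.reshape(-1, n_demes)
    log10_m = draws.mean(axis=0)

    d = pairwise_great_circle_km(
        coords[:, 0][:, None], coords[:, 1][:, None],
        lattice.lons[None, :], lattice.lats[None, :],
    )
    nearest = np.argmin(d, axis=1)
    far = d[np.arange(n_demes), nearest] > lattice.step_km
    if np.any(far):
        bad = int(np.flatnonzero(far)[0])
        raise ValueError(
            f"{demes_path}: row {bad} at ({coords[bad, 0]:.4f}, {coords[bad, 1]:.4f}) "
            f"is farther than one lattice step ({lattice.step_km:.1f} km) from every "
            "lattice center"
        )
    return MigrationSurface(lattice, nearest, log10_m, source="maps")


def write_maps_output(surface: MigrationSurface, mrates_path, demes_path) -> None:
    """Write a surface in the mRates.txt / demes.txt layout (round-trippable)."""
    with open(mrates_path, "w") as fh:
        fh.write(" ".join(f"{v:.17g}" for v in surface.log10_m) + "\n")
    with open(demes_path, "w") as fh:
        for d in surface.deme_ids:
            fh.write(
                f"{surface.lattice.lons[d]:.17g} {surface.lattice.lats[d]:.17g}\n"
            )


def average_replicates(surfaces, geometric: bool = False) -> MigrationSurface:
    """Average replicate surfaces per deme on the linear migration scale.

    The arithmetic mean of ``10^m`` across replicates is the default (the
    quantity of interest is the migration rate itself); a geometric mean —
    i.e. the arithmetic mean of the log10 rates — is available with
    ``geometric=True``.
    """
    surfaces = list(surfaces)
    if not surfaces:
        raise ValueError("need at least one surface")
    ref = surfaces[0]
    for s in surfaces[1:]:
        if not np.array_equal(s.deme_ids, ref.deme_ids):
            raise ValueError("replicate surfaces have mismatched deme support")
    stack = np.stack([s.log10_m for s in surfaces])
    if geometric:
        log10_m = stack.mean(axis=0)
    else:
        log10_m = np.log10((10.0 ** stack).mean(axis=0))
    return MigrationSurface(ref.lattice, ref.deme_ids.copy(), log10_m, source=ref.source)


def to_dispersal(surface: MigrationSurface, step_km: float, mode: str = "sqrt") -> DispersalSurface:
    """Convert migration rate to dispersal distance sigma.

    Default ``sqrt`` mode: sigma = step * sqrt(m); under diffusive movement
    the per-generation displacement variance scales as rate * step^2, so the
    RMS dispersal distance scales with the square root of the rate.  A
    ``linear`` mode (sigma = step * m) is also provided.
    """
    if step_km <= 0:
        raise ValueError("step_km must be positive")
    m = surface.m_linear
    if mode == "sqrt":
        sigma = step_km * np.sqrt(m)
    elif mode == "linear":
        sigma = step_km * m
    else:
        raise ValueError(f"unknown dispersal mode {mode!r}")
    return DispersalSurface(surface.lattice, surface.deme_ids.copy(), sigma)


def make_response(surface: MigrationSurface) -> ResponseVector:
    """Natural log of the linear migration rate, restricted to habitable demes."""
    m = surface.m_linear
    if np.any(m <= 0):
        raise ValueError("m_linear must be strictly positive for the log response")
    keep = surface.lattice.habitable[surface.deme_ids]
    return ResponseVector(surface.deme_ids[keep], np.log(m[keep]))


def baseline_surface(
    matrix: SharingMatrix,
    coords,
    lattice: DemeLattice,
    bandwidth_km: float = 200.0,
) -> MigrationSurface:
    """Kernel-smoothed local sharing intensity, z-scored across demes.

    For each habitable deme d, the sharing counts of all individual pairs
    are averaged with Gaussian weights in the great-circle distance between
    the deme center and the pair's great-circle midpoint:

        S(d) = sum_{i<j} w_ij(d) c_ij / sum_{i<j} w_ij(d),
        w_ij(d) = exp(-rho(d, mid_ij)^2 / (2 bw^2)).

    The z-score of S across habitable demes is returned as log10_m.  This is
    a heuristic smoke-test surface, not a migration-rate estimator.
    """
    if matrix.n < 2:
        raise ValueError("need at least 2 individuals")
    if bandwidth_km <= 0:
        raise ValueError("bandwidth_km must be positive")
    logger.info(
        "baseline_surface: heuristic kernel-smoothed surface (not publication-grade)"
    )
    coord_map = dict(coords.items()) if hasattr(coords, "items") else dict(coords)
    pts = [coord_map[i] for i in matrix.individual_ids]

    iu, ju = np.triu_indices(matrix.n, k=1)
    c = matrix.counts[iu, ju].astype(float)
    mids = [great_circle_midpoint(pts[i], pts[j]) for i, j in zip(iu, ju)]
    mlon = np.array([p.lon for p in mids])
    mlat = np.array([p.lat for p in mids])

    hab = lattice.habitable_ids
    d = pairwise_great_circle_km(
        lattice.lons[hab][:, None], lattice.lats[hab][:, None],
        mlon[None, :], mlat[None, :],
    )
    w = np.exp(-(d ** 2) / (2.0 * bandwidth_km ** 2))
    wsum = w.sum(axis=1)
    S = np.full(hab.size, np.nan)
    ok = wsum > 0
    S[ok] = (w[ok] @ c) / wsum[ok]
    if not np.all(ok):
        logger.warning(
            "baseline_surface: %d demes had all-zero kernel weights; "
            "imputed at the global mean (z = 0)", int((~ok).sum()),
        )
    sd = np.nanstd(S)
    if sd == 0 or np.all(np.isnan(S)):
        z = np.zeros(hab.size)
    else:
        z = (S - np.nanmean(S)) / sd
        z[~ok] = 0.0
    return MigrationSurface(lattice, hab, z, source="baseline")
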