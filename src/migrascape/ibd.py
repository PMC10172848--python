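"""IBD segment handling: parsing, length-stratification, sharing matrices.

Identity-by-descent (IBD) segments are genomic tracts two individuals
co-inherit from a common ancestor.  Segment length (in centimorgans) carries
time information: under a large-population approximation the expected
coalescent age of segments with length in [L1, L2] cM is

    T = (300/4) * (1/L1 + 1/L2)   generations,

so stratifying segments into length bins yields time-stratified sharing
matrices.  Segments shorter than 2 cM are discarded throughout because their
false-discovery rate is high.

The parser consumes the 8-column tab-delimited output of hap-ibd
(id1, hap1, id2, hap2, chrom, start_bp, end_bp, length_cM), plain or gzipped.
"""

from __future__ import annotations

import gzip
import logging
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .geo import GeoPoint

logger = logging.getLogger(__name__)

MIN_RELIABLE_CM = 2.0

__all__ = [
    "IBDSegment",
    "LengthBin",
    "SharingMatrix",
    "DEFAULT_BINS",
    "read_ibd",
    "expected_coalescent_generations",
    "bin_segments",
    "build_sharing_matrix",
    "write_maps_inputs",
    "read_maps_inputs",
    "export_network",
    "write_network_tsv",
]


@dataclass(frozen=True)
class IBDSegment:
    id1: str
    hap1: int
    id2: str
    hap2: int
    chrom: str
    start_bp: int
    end_bp: int
    length_cM: float

    def __post_init__(self) -> None:
        if self.id1 == self.id2:
            raise ValueError(
                f"within-individual IBD segment rejected (id {self.id1!r})"
            )
        if self.hap1 not in (1, 2) or self.hap2 not in (1, 2):
            raise ValueError(f"haplotype index outside {{1, 2}}: {self.hap1}, {self.hap2}")
        if self.start_bp >= self.end_bp:
            raise ValueError(
                f"segment start_bp {self.start_bp} must be < end_bp {self.end_bp}"
            )
        if self.length_cM <= 0:
            raise ValueError(f"nonpositive segment length {self.length_cM} cM")

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.id1, self.id2)))


@dataclass(frozen=True)
class LengthBin:
    """Half-open segment-length interval [lo_cM, hi_cM) in centimorgans."""

    lo_cM: float
    hi_cM: float  # may be math.inf

    def __post_init__(self) -> None:
        if self.lo_cM < MIN_RELIABLE_CM:
            raise ValueError(
                f"bin lower bound {self.lo_cM} cM below the {MIN_RELIABLE_CM} cM "
                "reliability floor"
            )
        if not self.lo_cM < self.hi_cM:
            raise ValueError(f"empty length bin [{self.lo_cM}, {self.hi_cM})")

    def __contains__(self, length_cM: float) -> bool:
        return self.lo_cM <= length_cM < self.hi_cM

    @property
    def label(self) -> str:
        hi = "inf" if math.isinf(self.hi_cM) else f"{self.hi_cM:g}"
        return f"{self.lo_cM:g}-{hi}"


DEFAULT_BINS: tuple[LengthBin, ...] = (
    LengthBin(2.0, 4.0),
    LengthBin(4.0, 6.0),
    LengthBin(6.0, math.inf),
)


def expected_coalescent_generations(bin: LengthBin) -> float:
    """Expected coalescent age (generations) of segments in a length bin.

    Uses the large-population closed form T = (300/4)(1/L1 + 1/L2); the
    reciprocal of an unbounded upper limit is zero.
    """
    if bin.lo_cM <= 0:
        raise ValueError("bin lower bound must be positive")
    inv_hi = 0.0 if math.isinf(bin.hi_cM) else 1.0 / bin.hi_cM
    return (300.0 / 4.0) * (1.0 / bin.lo_cM + inv_hi)


def read_ibd(path, allowed_ids=None) -> list[IBDSegment]:
    """Parse a hap-ibd segment file (8-column TSV, optionally gzipped).

    Rows whose individuals are not in ``allowed_ids`` (when given) are
    dropped; the dropped count is logged.  Malformed rows raise a ValueError
    naming the offending line number.
    """
    opener = gzip.open if _is_gzip(path) else open
    segments: list[IBDSegment] = []
    dropped = 0
    allowed = set(allowed_ids) if allowed_ids is not None else None
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 8:
                raise ValueError(
                    f"{path}: line {lineno}: expected 8 tab-delimited columns, "
                    f"got {len(fields)}"
                )
            id1, hap1, id2, hap2, chrom, start, end, length = fields
            try:
                seg = IBDSegment(
                    id1, int(hap1), id2, int(hap2), chrom, int(start), int(end),
                    float(length),
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            if allowed is not None and (id1 not in allowed or id2 not in allowed):
                dropped += 1
                continue
            segments.append(seg)
    if dropped:
        logger.info("read_ibd: dropped %d segments with ids outside allowed set", dropped)
    dup = sum(c - 1 for c in Counter(segments).values() if c > 1)
    if dup:
        logger.warning("read_ibd: %d exact duplicate segment rows retained", dup)
    return segments


def _is_gzip(path) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == b"\x1f\x8b"


def bin_segments(segments, bins=DEFAULT_BINS) -> list[list[IBDSegment]]:
    """Partition segments into half-open length bins [lo, hi).

    Segments shorter than the smallest lower bound are discarded (count
    logged).  Bins must be non-overlapping.
    """
    bins = list(bins)
    ordered = sorted(bins, key=lambda b: b.lo_cM)
    for a, b in zip(ordered, ordered[1:]):
        if a.hi_cM > b.lo_cM:
            raise ValueError(f"overlapping length bins [{a.label}] and [{b.label}]")
    out: list[list[IBDSegment]] = [[] for _ in bins]
    floor = min(b.lo_cM for b in bins)
    discarded = 0
    for seg in segments:
        if seg.length_cM < floor:
            discarded += 1
            continue
        for i, b in enumerate(bins):
            if seg.length_cM in b:
                out[i].append(seg)
                break
        else:
            discarded += 1
    if discarded:
        logger.info("bin_segments: discarded %d segments outside all bins", discarded)
    return out


@dataclass
class SharingMatrix:
    """Symmetric per-pair IBD segment counts over an ordered individual set."""

    individual_ids: tuple[str, ...]
    counts: np.ndarray
    bin: LengthBin | None = None

    def __post_init__(self) -> None:
        n = len(self.individual_ids)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (n, n):
            raise ValueError(f"counts shape {self.counts.shape} != ({n}, {n})")
        if not np.array_equal(self.counts, self.counts.T):
            raise ValueError("sharing matrix must be symmetric")
        if np.any(np.diag(self.counts) != 0):
            raise ValueError("sharing matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    def index_of(self, ind_id: str) -> int:
        return self.individual_ids.index(ind_id)


def build_sharing_matrix(segments, individual_ids) -> SharingMatrix:
    """Count segments per individual pair, summed over haplotype pairings."""
    ids = tuple(individual_ids)
    pos = {ind: i for i, ind in enumerate(ids)}
    counts = np.zeros((len(ids), len(ids)), dtype=np.int64)
    for seg in segments:
        for ind in (seg.id1, seg.id2):
            if ind not in pos:
                raise ValueError(f"segment id {ind!r} absent from individual_ids")
        i, j = pos[seg.id1], pos[seg.id2]
        counts[i, j] += 1
        counts[j, i] += 1
    return SharingMatrix(ids, counts)


def write_maps_inputs(matrix: SharingMatrix, coords, out_prefix) -> tuple[str, str]:
    """Write the sharing matrix and coordinates in MAPS input layout.

    ``coords`` maps individual id -> GeoPoint (a dict, or a pandas Series).
    Writes ``<prefix>.sims`` (N x N whitespace-delimited integer matrix) and
    ``<prefix>.coord`` (N rows of "lon lat"), both in matrix id order.
    """
    coord_map = dict(coords.items()) if hasattr(coords, "items") else dict(coords)
    mat_ids, coord_ids = set(matrix.individual_ids), set(coord_map)
    if mat_ids != coord_ids:
        diff = sorted(mat_ids.symmetric_difference(coord_ids))
        raise ValueError(f"matrix/coords id mismatch; symmetric difference: {diff}")
    sims_path = f"{out_prefix}.sims"
    coord_path = f"{out_prefix}.coord"
    with open(sims_path, "w") as fh:
        for row in matrix.counts:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")
    with open(coord_path, "w") as fh:
        for ind in matrix.individual_ids:
            p = coord_map[ind]
            fh.write(f"{p.lon:.10g} {p.lat:.10g}\n")
    return sims_path, coord_path


def read_maps_inputs(prefix, individual_ids) -> tuple[SharingMatrix, list[GeoPoint]]:
    """Round-trip reader for :func:`write_maps_inputs` outputs."""
    counts = np.loadtxt(f"{prefix}.sims", dtype=np.int64, ndmin=2)
    coords = np.loadtxt(f"{prefix}.coord", ndmin=2)
    pts = [GeoPoint(float(lon), float(lat)) for lon, lat in coords]
    return SharingMatrix(tuple(individual_ids), counts), pts


def export_network(segments, min_cM: float = 6.0) -> list[tuple[str, str, int]]:
    """Undirected IBD-sharing edge list for network visualization.

    One edge per individual pair with at least one segment strictly longer
    than ``min_cM``; the weight is the number of such segments.  Pairs are
    ordered lexicographically, as is the edge list.
    """
    weights: Counter = Counter()
    for seg in segments:
        if seg.length_cM > min_cM:
            weights[seg.pair] += 1
    return [(a, b, w) for (a, b), w in sorted(weights.items())]


def write_network_tsv(edges, path) -> None:
    with open(path, "w") as fh:
        fh.write("id1\tid2\tshared_count\n")
        for a, b, w in edges:
            fh.write(f"{a}\t{b}\t{w}\n")
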