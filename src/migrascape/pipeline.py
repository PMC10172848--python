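"""End-to-end orchestration: segments -> surfaces -> predictors -> regression.

A run is driven by a YAML config.  Per IBD length bin it builds the sharing
matrix, obtains a migration surface (external MCMC outputs when provided,
otherwise the labelled heuristic baseline), regresses the log-migration
response on the shared predictor table (tune, full fit, k-fold CV, and the
with/without-kernel comparison when requested), and writes a report shaped
like the regression-summary tables of the analyses this tool supports: one
row per (length bin x kernel inclusion) with RSQ, r_train, r_test means and
SDs, the full-data RSQ and r, and the top variables by permutation
importance.

Config keys (YAML):
  bbox: [lon_tl, lat_tl, lon_br, lat_br]      # top-left, bottom-right
  target_demes: 400
  bins: [[2, 4], [4, 6], [6, "inf"]]
  segments: path.ibd[.gz]          coords: samples.tsv (id lon lat)
  rasters: [a.asc, b.tif, ...]     hull_points: [family1.tsv, ...]
  maps: {"2-4": [[mRates, demes], ...replicates], ...}   # or baseline: true
  baseline_bandwidth_km: 200       kernel_bandwidth_km: 200
  include_kernel: true             compare_kernel: true
  k_folds: 10                      locoh_k: 10
  tune: true                       n_trees: 1000
  seed: 0
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geo import BoundingBox, DemeLattice, GeoPoint, assign_individuals, build_lattice
from .ibd import DEFAULT_BINS, LengthBin, bin_segments, build_sharing_matrix, read_ibd
from .migration import (
    average_replicates,
    baseline_surface,
    make_response,
    read_maps_output,
)
from .predictors import (
    DEFAULT_BANDWIDTH_KM,
    DEFAULT_LOCOH_K,
    KERNEL_COLUMN,
    assemble_table,
    locoh_hulls,
    read_raster,
)
from .rf import MigrationForest, ModelConfig
from .synthetic import IBDGenParams, TruthSpec, generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "validate", "run", "synth_run"]


@dataclass
class PipelineConfig:
    bbox: BoundingBox = None
    target_demes: int = 400
    bins: tuple[LengthBin, ...] = DEFAULT_BINS
    segments: str | None = None
    coords: str | None = None
    rasters: tuple[str, ...] = ()
    hull_points: tuple[str, ...] = ()
    maps: dict = field(default_factory=dict)  # bin label -> [[mrates, demes], ...]
    baseline: bool = False
    baseline_bandwidth_km: float = DEFAULT_BANDWIDTH_KM
    kernel_bandwidth_km: float = DEFAULT_BANDWIDTH_KM
    include_kernel: bool = True
    compare_kernel: bool = True
    k_folds: int = 10
    locoh_k: int = DEFAULT_LOCOH_K
    tune: bool = True
    n_trees: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, base_dir=os.path.dirname(os.path.abspath(path)))

    @classmethod
    def from_dict(cls, raw: dict, base_dir: str = ".") -> "PipelineConfig":
        def _p(x):
            return x if os.path.isabs(x) else os.path.join(base_dir, x)

        kwargs: dict = {}
        if "bbox" in raw:
            lon1, lat1, lon2, lat2 = raw["bbox"]
            kwargs["bbox"] = BoundingBox(GeoPoint(lon1, lat1), GeoPoint(lon2, lat2))
        if "bins" in raw:
            kwargs["bins"] = tuple(
                LengthBin(float(lo), math.inf if str(hi).lower() in ("inf", "none") else float(hi))
                for lo, hi in raw["bins"]
            )
        for key in ("target_demes", "baseline", "include_kernel", "compare_kernel",
                    "k_folds", "locoh_k", "tune", "n_trees", "seed",
                    "kernel_bandwidth_km", "baseline_bandwidth_km"):
            if key in raw:
                kwargs[key] = raw[key]
        if "segments" in raw:
            kwargs["segments"] = _p(raw["segments"])
        if "coords" in raw:
            kwargs["coords"] = _p(raw["coords"])
        if "rasters" in raw:
            kwargs["rasters"] = tuple(_p(r) for r in raw["rasters"])
        if "hull_points" in raw:
            kwargs["hull_points"] = tuple(_p(h) for h in raw["hull_points"])
        if "maps" in raw:
            kwargs["maps"] = {
                label: [[_p(m), _p(d)] for m, d in reps]
                for label, reps in raw["maps"].items()
            }
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bbox"] = (
            [self.bbox.top_left.lon, self.bbox.top_left.lat,
             self.bbox.bottom_right.lon, self.bbox.bottom_right.lat]
            if self.bbox else None
        )
        d["bins"] = [[b.lo_cM, "inf" if math.isinf(b.hi_cM) else b.hi_cM] for b in self.bins]
        return d


def validate(config: PipelineConfig) -> PipelineConfig:
    """Aggregate all config problems into one error report (not fail-fast)."""
    problems: list[str] = []
    if config.bbox is None:
        problems.append("bbox is required")
    for name in ("segments", "coords"):
        path = getattr(config, name)
        if path is None:
            problems.append(f"{name} path is required")
        elif not os.path.exists(path):
            problems.append(f"{name} path does not exist: {path}")
    for r in config.rasters:
        if not os.path.exists(r):
            problems.append(f"raster path does not exist: {r}")
    for h in config.hull_points:
        if not os.path.exists(h):
            problems.append(f"hull point path does not exist: {h}")
    try:
        bin_segments([], config.bins)
    except ValueError as exc:
        problems.append(str(exc))
    if not config.baseline:
        if not config.maps:
            problems.append("either baseline: true or maps outputs must be given")
        for b in config.bins:
            reps = config.maps.get(b.label)
            if not reps:
                problems.append(f"missing MAPS outputs for bin {b.label}")
                continue
            for mrates, demes in reps:
                for p in (mrates, demes):
                    if not os.path.exists(p):
                        problems.append(f"bin {b.label}: missing MAPS file {p}")
    if config.k_folds < 2:
        problems.append("k_folds must be at least 2")
    if problems:
        raise ValueError(
            "pipeline config validation failed:\n  - " + "\n  - ".join(problems)
        )
    return config


def _read_coords(path) -> tuple[list[str], list[GeoPoint]]:
    ids, pts = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            try:
                lon, lat = float(parts[-2]), float(parts[-1])
            except ValueError:
                continue
            ids.append(parts[0])
            pts.append(GeoPoint(lon, lat))
    return ids, pts


def run(config: PipelineConfig, outdir) -> pd.DataFrame:
    """Execute the full pipeline; writes report files and returns the report."""
    validate(config)
    os.makedirs(outdir, exist_ok=True)
    log_lines: list[str] = []

    def log(msg):
        logger.info(msg)
        log_lines.append(msg)

    lattice = build_lattice(config.bbox, config.target_demes)
    log(f"lattice: {lattice.n_demes} demes, step {lattice.step_km:.1f} km")
    lattice.to_tsv(os.path.join(outdir, "lattice.tsv"))

    ids, pts = _read_coords(config.coords)
    coords = dict(zip(ids, pts))
    log(f"coords: {len(ids)} individuals")
    segments = read_ibd(config.segments, allowed_ids=set(ids))
    log(f"segments: {len(segments)} read")
    per_bin = bin_segments(segments, config.bins)

    rasters = [read_raster(p) for p in config.rasters]
    hull_sets = []
    for path in config.hull_points:
        from .predictors import read_points_tsv

        name = os.path.splitext(os.path.basename(path))[0]
        hull_sets.append(locoh_hulls(read_points_tsv(path), config.locoh_k, name))
    table = assemble_table(
        lattice, rasters, hull_sets, pts,
        include_kernel=config.include_kernel,
        bandwidth_km=config.kernel_bandwidth_km,
    )
    log(f"predictors: {table.shape[0]} demes x {table.shape[1]} columns")
    table.to_csv(os.path.join(outdir, "predictors.tsv"), sep="\t", float_format="%.10g")

    report_rows = []
    for b, segs in zip(config.bins, per_bin):
        prefix = f"bin {b.label}"
        log(f"{prefix}: {len(segs)} segments")
        matrix = build_sharing_matrix(segs, tuple(ids))
        if config.baseline:
            surface = baseline_surface(matrix, coords, lattice, config.baseline_bandwidth_km)
            from .synthetic import make_response_from_z

            response = make_response_from_z(surface)
        else:
            reps = [
                read_maps_output(mrates, demes, lattice)
                for mrates, demes in config.maps[b.label]
            ]
            surface = average_replicates(reps)
            response = make_response(surface)
        surface.to_tsv(os.path.join(outdir, f"surface_{b.label}.tsv"))

        sub = table.loc[table.index.intersection(response.deme_ids)]
        resp = pd.Series(response.y, index=pd.Index(response.deme_ids, name="deme_id"))
        resp = resp.loc[sub.index]
        model = MigrationForest(sub, resp)
        cfg = ModelConfig(n_trees=config.n_trees, seed=config.seed)
        if config.tune:
            mtry, nodesize = model.tune(seed=config.seed, n_trees=config.n_trees)
            cfg = ModelConfig(config.n_trees, mtry, nodesize, config.seed)
            log(f"{prefix}: tuned mtry={mtry} nodesize={nodesize}")

        variants = [("All", model)]
        if config.include_kernel and config.compare_kernel:
            reduced = MigrationForest(sub.drop(columns=[KERNEL_COLUMN]), resp)
            variants.append(("Excluded kernel", reduced))
        for label, mdl in variants:
            full = mdl.fit(cfg)
            cv = mdl.cross_validate(config.k_folds, cfg, fold_seed=config.seed)
            report_rows.append({
                "variables": label,
                "interval": b.label,
                "rsq_mean": cv.mean("rsq_pct"), "rsq_sd": cv.sd("rsq_pct"),
                "r_train_mean": cv.mean("r_train"), "r_train_sd": cv.sd("r_train"),
                "r_test_mean": cv.mean("r_test"), "r_test_sd": cv.sd("r_test"),
                "rsq_full": full.rsq_pct,
                "r_full": full.r_full,
                "top_variables": "; ".join(full.top_variables(4)),
            })
            suffix = "" if label == "All" else "_nokernel"
            with open(os.path.join(outdir, f"fit_{b.label}{suffix}.json"), "w") as fh:
                json.dump(full.to_json_dict(), fh, indent=1, sort_keys=True)
            cv.folds.to_csv(
                os.path.join(outdir, f"cv_{b.label}{suffix}.tsv"),
                sep="\t", float_format="%.10g",
            )
        log(f"{prefix}: done")

    report = pd.DataFrame(report_rows)
    report.to_csv(os.path.join(outdir, "report.tsv"), sep="\t", index=False,
                  float_format="%.10g")
    provenance = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "log": log_lines,
    }
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(
            {"provenance": provenance, "rows": report.to_dict(orient="records")},
            fh, indent=1, sort_keys=True,
        )
    with open(os.path.join(outdir, "log.txt"), "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return report


def synth_run(
    seed: int,
    outdir,
    *,
    target_demes: int = 400,
    n_individuals: int = 200,
    n_layers: int = 20,
    k_folds: int = 10,
    n_trees: int = 1000,
    tune: bool = True,
) -> pd.DataFrame:
    """Generate a synthetic dataset on disk and run the pipeline end-to-end.

    The synthetic path exercises the same file formats the real pipeline
    consumes: hap-ibd style segments, a coordinate table, ASCII-grid
    rasters, and the baseline surface in place of external MCMC output.
    """
    os.makedirs(outdir, exist_ok=True)
    datadir = os.path.join(outdir, "input")
    os.makedirs(datadir, exist_ok=True)
    truth = TruthSpec(n_layers=n_layers, seed=seed)
    params = IBDGenParams(seed=seed + 1)
    ds = generate_dataset(
        truth, params, target_demes=target_demes, n_individuals=n_individuals,
    )
    from .predictors import write_raster

    raster_paths = []
    for layer in ds.layers:
        p = os.path.join(datadir, f"{layer.name}.asc")
        write_raster(layer, p)
        raster_paths.append(p)
    seg_path = os.path.join(datadir, "segments.ibd")
    with open(seg_path, "w") as fh:
        for s in ds.segments:
            fh.write(
                f"{s.id1}\t{s.hap1}\t{s.id2}\t{s.hap2}\t{s.chrom}\t"
                f"{s.start_bp}\t{s.end_bp}\t{s.length_cM:.6g}\n"
            )
    coord_path = os.path.join(datadir, "coords.tsv")
    with open(coord_path, "w") as fh:
        fh.write("id\tlon\tlat\n")
        for ind, p in zip(ds.individual_ids, ds.individuals):
            fh.write(f"{ind}\t{p.lon:.10g}\t{p.lat:.10g}\n")
    ds.surface.to_tsv(os.path.join(datadir, "true_surface.tsv"))
    with open(os.path.join(datadir, "truth.json"), "w") as fh:
        json.dump(
            {"truth": dataclasses.asdict(truth), "ibd": dataclasses.asdict(params),
             "explainable_variance": ds.explainable_variance},
            fh, indent=1, sort_keys=True,
        )

    bb = ds.lattice.bbox
    config = PipelineConfig(
        bbox=bb, target_demes=target_demes, segments=seg_path, coords=coord_path,
        rasters=tuple(raster_paths), baseline=True, k_folds=k_folds,
        n_trees=n_trees, tune=tune, seed=seed,
    )
    return run(config, outdir)
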