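"""End-to-end orchestration: harmonize, trend maps, cover transitions,
fishnet sampling, sensor comparison, and the geographical-detector report.

Stages are gated by input presence: a run with only an NDVI stack produces
trend and cover products; adding a secondary (coarser) stack enables the
sensor comparison; adding a driver sample table (or driver rasters) enables
the detector report.  Every file written is listed in the run manifest with
a SHA-256 checksum, and all randomness derives from the single seed recorded
there, so re-running an unchanged config reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cover import CoverScheme, class_area_stats, classify_ndvi, transfer_matrix
from .geodetector import detector_report
from .raster import (RasterStack, harmonize, make_fishnet, read_raster,
                     sample_at_points, write_raster)
from .sensors import compare_stack_pair
from .trend import stack_std, trend_class_areas, trend_raster

log = logging.getLogger("vegtrend")

_FLOAT_FMT = "%.10g"


@dataclasses.dataclass
class RunConfig:
    output_dir: Path
    ndvi_stack: Path
    secondary_stack: Path | None = None
    drivers_table: Path | None = None
    drivers_response: str = "ndvi"
    drivers_categorical: tuple[str, ...] = ()
    fishnet_spacing: float = 3000.0
    min_epochs: int = 4
    k_min: int = 3
    k_max: int = 8
    permutations: int = 0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        drivers = raw.get("drivers", {}) or {}
        gd = raw.get("geodetector", {}) or {}
        cfg = cls(
            output_dir=Path(raw["output_dir"]),
            ndvi_stack=Path(raw["ndvi_stack"]),
            secondary_stack=Path(raw["secondary_stack"]) if raw.get("secondary_stack") else None,
            drivers_table=Path(drivers["table"]) if drivers.get("table") else None,
            drivers_response=drivers.get("response", "ndvi"),
            drivers_categorical=tuple(drivers.get("categorical", [])),
            fishnet_spacing=float(raw.get("fishnet_spacing", 3000.0)),
            min_epochs=int(raw.get("min_epochs", 4)),
            k_min=int(gd.get("k_min", 3)),
            k_max=int(gd.get("k_max", 8)),
            permutations=int(gd.get("permutations", 0)),
            seed=int(raw.get("seed", 0)),
        )
        for p in (cfg.ndvi_stack, cfg.secondary_stack, cfg.drivers_table):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config references missing file: {p}")
        return cfg


def load_stack_manifest(path: str | Path) -> RasterStack:
    """Read a stack from a manifest CSV with columns ``path, year``."""
    man = pd.read_csv(path)
    if not {"path", "year"} <= set(man.columns):
        raise ValueError(f"{path}: manifest needs 'path' and 'year' columns")
    man = man.sort_values("year")
    base = Path(path).parent
    grids = [read_raster(base / p if not Path(p).is_absolute() else p)
             for p in man["path"]]
    return RasterStack(grids, man["year"].to_numpy(dtype=float))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    return path


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all applicable stages; returns the run manifest dict."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    warnings_log: list[str] = []

    def emit(path: Path) -> None:
        written.append(path)
        log.info("wrote %s", path)

    stage = "load_stack"
    try:
        stack = load_stack_manifest(cfg.ndvi_stack)

        # --- trend + SD maps
        stage = "trend"
        maps = trend_raster(stack, min_epochs=cfg.min_epochs)
        for name, grid in maps.items():
            emit(write_raster(grid, out / f"trend_{name}.tif"))
        areas = trend_class_areas(maps["trend_class"])
        emit(_write_csv(pd.DataFrame(
            [{"trend_class": k, "percent": v} for k, v in sorted(areas.items())]),
            out / "trend_class_percent.csv"))
        emit(write_raster(stack_std(stack), out / "ndvi_std.tif"))

        # --- cover classes + transfer matrix (first vs last epoch)
        stage = "cover"
        scheme = CoverScheme()
        cls_first = classify_ndvi(stack.grids[0], scheme)
        cls_last = classify_ndvi(stack.grids[-1], scheme)
        emit(write_raster(cls_first, out / "cover_t1.tif"))
        emit(write_raster(cls_last, out / "cover_t2.tif"))
        emit(_write_csv(class_area_stats(cls_first, scheme), out / "cover_area_t1.csv"))
        emit(_write_csv(class_area_stats(cls_last, scheme), out / "cover_area_t2.csv"))
        tm = transfer_matrix(cls_first, cls_last, scheme)
        tm_df = tm.to_frame().reset_index(names="from_class")
        emit(_write_csv(tm_df, out / "transfer_matrix.csv"))

        # --- fishnet sampling of the temporal-mean NDVI
        stage = "fishnet"
        t = stack.transform
        extent = (t.x0, t.y0 - stack.shape[0] * t.cell_size,
                  t.x0 + stack.shape[1] * t.cell_size, t.y0)
        net = make_fishnet(extent, cfg.fishnet_spacing)
        cube = stack.as_cube()
        with np.errstate(all="ignore"):
            mean_vals = np.nanmean(cube, axis=0)
        mean_grid = dataclasses.replace(
            stack.grids[0], values=np.where(np.isfinite(mean_vals), mean_vals, np.nan),
            nodata_mask=~np.isfinite(mean_vals))
        sample = sample_at_points({"ndvi_mean": mean_grid}, net.points)
        emit(_write_csv(sample.table, out / "fishnet_samples.csv"))

        # --- sensor comparison
        if cfg.secondary_stack is not None:
            stage = "sensor_comparison"
            coarse = load_stack_manifest(cfg.secondary_stack)
            fine_on_coarse = RasterStack(
                [harmonize(g, coarse.transform, coarse.shape, "continuous")
                 for g in stack.grids], stack.times)
            fit, per_epoch = compare_stack_pair(fine_on_coarse, coarse, net)
            emit(_write_csv(pd.DataFrame([{
                "sensor_pair": f"{fit.x_name}->{fit.y_name}",
                "n_used": fit.n_used, "slope": fit.slope,
                "intercept": fit.intercept, "r2": fit.r2,
                "pearson": fit.pearson}]), out / "sensor_fit.csv"))
            if len(per_epoch):
                emit(_write_csv(per_epoch, out / "sensor_fit_per_epoch.csv"))

        # --- geographical detector
        if cfg.drivers_table is not None:
            stage = "geodetector"
            table = pd.read_csv(cfg.drivers_table)
            p_method = "perm" if cfg.permutations > 0 else "ncf"
            report = detector_report(
                table, cfg.drivers_response,
                factor_types={c: "categorical" for c in cfg.drivers_categorical},
                k_range=range(cfg.k_min, cfg.k_max + 1),
                p_method=p_method, n_perm=cfg.permutations, seed=cfg.seed)
            for name, df in report.items():
                emit(_write_csv(df, out / f"detector_{name}.csv"))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": {k: str(v) if isinstance(v, Path) else v
                   for k, v in dataclasses.asdict(cfg).items()},
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in written},
        "warnings": warnings_log,
    }
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
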