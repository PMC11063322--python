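"""Seeded generators of raster scenes and sample tables with known truth.

Three generators cover the pipeline's inputs:

* :func:`gen_trend_stack` — an NDVI time series whose pixels follow
  ``base(x,y) + slope(x,y) * (t - t0) + Normal(0, noise_sd)``, with the slope
  laid out in rectangular regions so per-region truth areas are exact;
* :func:`gen_strata_response` — a stratified response
  ``y_i = mu_h(i) + Normal(0, sigma_w)`` with the closed-form theoretical
  q* = Var_b / (Var_b + sigma_w^2), Var_b = sum_h w_h (mu_h - mu_bar)^2, plus
  a monotone continuous covariate carrying the same stratification;
* :func:`gen_sensor_pair` — a coarse-sensor rendition of a fine stack:
  block-mean aggregation, then an affine link ``gain * v + bias`` plus
  sensor noise.

All draws go through one ``numpy`` Generator per call, so outputs are
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .geodetector import StrataAssignment
from .raster import GridTransform, RasterGrid, RasterStack

__all__ = [
    "TrendSceneConfig",
    "StrataSceneConfig",
    "SensorPairConfig",
    "gen_trend_stack",
    "gen_strata_response",
    "gen_sensor_pair",
]


@dataclasses.dataclass
class TrendSceneConfig:
    """NDVI trend scene: rectangular slope regions plus Gaussian noise.

    ``region_slopes`` maps each of ``n_regions`` vertical bands (left to
    right) to a slope in NDVI units per year; ``base`` is the scene-wide mean
    NDVI at the first epoch.
    """

    shape: tuple[int, int] = (100, 100)
    cell_size: float = 250.0
    years: Sequence[float] = tuple(range(2016, 2023))
    base: float = 0.3
    region_slopes: Sequence[float] = (0.0, 0.02)
    noise_sd: float = 0.01
    nodata_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.years) < 4:
            raise ValueError("need >= 4 epochs for a trend scene")
        if not (0 <= self.nodata_fraction < 1):
            raise ValueError("nodata_fraction must be in [0, 1)")


@dataclasses.dataclass
class StrataSceneConfig:
    """Stratified response sample with known theoretical q."""

    n: int = 1000
    strata_weights: Sequence[float] = (0.5, 0.5)
    strata_means: Sequence[float] = (0.0, 2.0)
    within_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.strata_weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("strata weights must sum to 1")
        if len(self.strata_weights) != len(self.strata_means):
            raise ValueError("one mean per stratum required")
        if not (self.within_sd > 0):
            raise ValueError("within_sd must be > 0")

    @property
    def q_theoretical(self) -> float:
        w = np.asarray(self.strata_weights, dtype=float)
        mu = np.asarray(self.strata_means, dtype=float)
        mbar = float(np.sum(w * mu))
        var_b = float(np.sum(w * (mu - mbar) ** 2))
        return var_b / (var_b + self.within_sd ** 2)


@dataclasses.dataclass
class SensorPairConfig:
    """Affine coarse-sensor link: aggregate, scale, bias, noise."""

    aggregation_factor: int = 1
    gain: float = 1.0
    bias: float = 0.0
    sensor_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.aggregation_factor < 1:
            raise ValueError("aggregation_factor must be >= 1")


def _region_map(shape: tuple[int, int], n_regions: int) -> np.ndarray:
    """Vertical-band region ids 0..n_regions-1, equal widths (last band wider
    if the column count is not divisible)."""
    rows, cols = shape
    width = cols // n_regions
    region = np.zeros(shape, dtype=int)
    for r in range(n_regions):
        lo = r * width
        hi = cols if r == n_regions - 1 else (r + 1) * width
        region[:, lo:hi] = r
    return region


def gen_trend_stack(cfg: TrendSceneConfig
                    ) -> tuple[RasterStack, RasterGrid, RasterGrid]:
    """Generate a trend scene; returns (stack, true_slope, region_id)."""
    rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.shape
    transform = GridTransform(0.0, rows * cfg.cell_size, cfg.cell_size)
    region = _region_map(cfg.shape, len(cfg.region_slopes))
    slope = np.asarray(cfg.region_slopes, dtype=float)[region]
    years = np.asarray(cfg.years, dtype=float)
    t0 = years[0]
    nodata = (rng.random(cfg.shape) < cfg.nodata_fraction
              if cfg.nodata_fraction > 0 else np.zeros(cfg.shape, dtype=bool))
    grids = []
    for t in years:
        vals = cfg.base + slope * (t - t0)
        if cfg.noise_sd > 0:
            vals = vals + rng.normal(0.0, cfg.noise_sd, cfg.shape)
        vals = np.where(nodata, np.nan, vals)
        grids.append(RasterGrid(vals, transform, nodata.copy(), "synthetic"))
    stack = RasterStack(grids, years)
    truth_slope = RasterGrid(np.where(nodata, np.nan, slope), transform,
                             nodata.copy(), "synthetic")
    region_grid = RasterGrid(region.astype(float), transform,
                             np.zeros(cfg.shape, dtype=bool), "synthetic")
    return stack, truth_slope, region_grid


def gen_strata_response(cfg: StrataSceneConfig
                        ) -> tuple[np.ndarray, StrataAssignment, np.ndarray, float]:
    """Generate (y, strata, x_continuous, q_theoretical).

    ``x_continuous`` is a monotone carrier of the stratification: stratum h
    occupies the interval [h-1, h) with a uniform jitter, so any reasonable
    discretization can recover the strata.
    """
    rng = np.random.default_rng(cfg.seed)
    w = np.asarray(cfg.strata_weights, dtype=float)
    mu = np.asarray(cfg.strata_means, dtype=float)
    labels = rng.choice(np.arange(1, w.size + 1), size=cfg.n, p=w)
    y = mu[labels - 1] + rng.normal(0.0, cfg.within_sd, cfg.n)
    x = (labels - 1) + rng.random(cfg.n)
    return y, StrataAssignment(labels, source="synthetic"), x, cfg.q_theoretical


def gen_sensor_pair(fine: RasterStack, cfg: SensorPairConfig) -> RasterStack:
    """Coarse-sensor stack derived from a fine stack by block-mean
    aggregation followed by the affine sensor link plus noise.

    The aggregation factor must divide both grid dimensions; trailing rows or
    columns are truncated otherwise.
    """
    rng = np.random.default_rng(cfg.seed)
    f = cfg.aggregation_factor
    src_t = fine.transform
    rows, cols = fine.shape
    out_r, out_c = rows // f, cols // f
    coarse_t = GridTransform(src_t.x0, src_t.y0, src_t.cell_size * f)
    grids = []
    for g in fine.grids:
        m = g.masked()[: out_r * f, : out_c * f]
        blocks = m.reshape(out_r, f, out_c, f).swapaxes(1, 2)
        with np.errstate(all="ignore"):
            agg = np.nanmean(blocks.reshape(out_r, out_c, f * f), axis=-1)
        vals = cfg.gain * agg + cfg.bias
        if cfg.sensor_noise_sd > 0:
            vals = vals + rng.normal(0.0, cfg.sensor_noise_sd, vals.shape)
        mask = ~np.isfinite(vals)
        vals = np.where(mask, np.nan, vals)
        grids.append(RasterGrid(vals, coarse_t, mask, fine.grids[0].crs_tag))
    return RasterStack(grids, fine.times.copy())
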