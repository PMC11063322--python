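"""Cross-sensor NDVI agreement: paired sampling and conversion-equation fits.

Two sensors observing the same scene at different resolutions are compared by
harmonizing both to a common grid, sampling them at the same fishnet points,
and fitting the ordinary least squares conversion equation
``y = slope * x + intercept`` together with the coefficient of determination
R² and Pearson's correlation.  For a simple linear fit R² equals the squared
Pearson correlation, which is asserted on every fit.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .raster import FishnetSample, RasterStack, sample_at_points

__all__ = ["PairedSample", "FitResult", "fit_conversion", "compare_stack_pair"]


class SensorFitError(ValueError):
    """Degenerate paired sample (too few points, constant predictor)."""


@dataclasses.dataclass
class PairedSample:
    """Co-located NDVI from two sensors; rows with missing values dropped."""

    x: np.ndarray
    y: np.ndarray
    x_name: str = "sensor_a"
    y_name: str = "sensor_b"
    n_dropped: int = 0


@dataclasses.dataclass
class FitResult:
    slope: float
    intercept: float
    r2: float
    pearson: float
    slope_se: float
    intercept_se: float
    n_used: int
    x_name: str = "sensor_a"
    y_name: str = "sensor_b"


def fit_conversion(pairs: PairedSample) -> FitResult:
    """OLS conversion equation between two sensors' NDVI samples."""
    x = np.asarray(pairs.x, dtype=float)
    y = np.asarray(pairs.y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise SensorFitError(f"need >= 3 paired points, got {x.size}")
    if np.ptp(x) == 0:
        raise SensorFitError("predictor sensor values are constant")
    res = stats.linregress(x, y)
    return FitResult(slope=float(res.slope), intercept=float(res.intercept),
                     r2=float(res.rvalue) ** 2, pearson=float(res.rvalue),
                     slope_se=float(res.stderr),
                     intercept_se=float(res.intercept_stderr),
                     n_used=int(x.size),
                     x_name=pairs.x_name, y_name=pairs.y_name)


def compare_stack_pair(fine: RasterStack, coarse: RasterStack,
                       fishnet: FishnetSample, pooled: bool = True,
                       x_name: str = "fine", y_name: str = "coarse"
                       ) -> tuple[FitResult, pd.DataFrame]:
    """Fit the conversion equation between two harmonized stacks.

    Both stacks are sampled at the fishnet points at every shared epoch.  The
    default pools all epochs into one scatter (one fit over point × epoch
    pairs); ``pooled=False`` returns per-epoch fits in the table and the
    pooled fit as the headline result regardless.  The finer sensor is the
    predictor (x) by convention; direction is recorded in the result.
    """
    fine.grids[0].require_same_geometry(coarse.grids[0], "compare_stack_pair")
    shared = [i for i, t in enumerate(fine.times) if t in set(coarse.times)]
    if not shared:
        raise SensorFitError("stacks share no epochs")
    coarse_index = {t: i for i, t in enumerate(coarse.times)}
    xs, ys, epoch_rows = [], [], []
    for i in shared:
        t = fine.times[i]
        tab = sample_at_points({"val_a": fine.grids[i],
                                "val_b": coarse.grids[coarse_index[t]]},
                               fishnet.points).table
        valid = tab[tab["valid"]]
        xs.append(valid["val_a"].to_numpy(dtype=float))
        ys.append(valid["val_b"].to_numpy(dtype=float))
        if not pooled and len(valid) >= 3 and valid["val_a"].nunique() > 1:
            f = fit_conversion(PairedSample(valid["val_a"].to_numpy(dtype=float),
                                            valid["val_b"].to_numpy(dtype=float),
                                            x_name, y_name))
            epoch_rows.append({"time": t, "n_used": f.n_used,
                               "slope": f.slope, "intercept": f.intercept,
                               "r2": f.r2, "pearson": f.pearson})
    x_all = np.concatenate(xs)
    y_all = np.concatenate(ys)
    if x_all.size == 0:
        raise SensorFitError("no overlapping valid fishnet points")
    fit = fit_conversion(PairedSample(x_all, y_all, x_name, y_name))
    per_epoch = pd.DataFrame(epoch_rows)
    return fit, per_epoch
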