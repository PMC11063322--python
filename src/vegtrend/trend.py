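"""Per-pixel Theil–Sen slope, Mann–Kendall significance, and trend classes.

The trend magnitude is the Theil–Sen estimator

    beta = median over i < j of (v_j - v_i) / (t_j - t_i),

a robust slope in response-units per year.  Significance comes from the
Mann–Kendall test: S is the sum of sign(v_j - v_i) over all pairs, Var(S)
carries the tie correction

    Var(S) = [n(n-1)(2n+5) - sum_t t(t-1)(2t+5)] / 18

over tie-group sizes t, and Z applies the +/-1 continuity correction.  The
joint (sign(beta), |Z|) label against the nodes 1.65 / 1.96 / 2.58 gives
eight signed trend classes plus a no-change code 0.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .raster import RasterGrid, RasterStack, RasterError

__all__ = [
    "TrendResult",
    "TrendClassTable",
    "TREND_CLASS_LABELS",
    "sen_slope",
    "mk_test",
    "classify_trend",
    "trend_raster",
    "stack_std",
]


@dataclasses.dataclass(frozen=True)
class TrendClassTable:
    """Z-score nodes and labels of the eight-class trend scheme.

    Codes: positive slopes map to 1–4 (4 = most significant), negative slopes
    to −1…−4, and a zero slope (or undefined pixel) to 0.
    """

    thresholds: tuple[float, float, float] = (1.65, 1.96, 2.58)
    alpha: float = 0.05

    def __post_init__(self) -> None:
        t = self.thresholds
        if not (t[0] < t[1] < t[2]):
            raise ValueError("thresholds must be strictly increasing")


TREND_CLASS_LABELS = {
    4: "highly significant increase",
    3: "significant increase",
    2: "slightly significant increase",
    1: "not significant increase",
    0: "no change",
    -1: "not significant decrease",
    -2: "slightly significant decrease",
    -3: "significant decrease",
    -4: "highly significant decrease",
}


@dataclasses.dataclass
class TrendResult:
    beta: float
    S: int
    varS: float
    Z: float
    trend_class: int


def _clean(values: Sequence[float],
           times: Sequence[float] | None = None) -> tuple[np.ndarray, np.ndarray]:
    v = np.asarray(values, dtype=float)
    t = (np.arange(v.size, dtype=float) if times is None
         else np.asarray(times, dtype=float))
    if t.shape != v.shape:
        raise ValueError("values and times must have equal length")
    ok = np.isfinite(v) & np.isfinite(t)
    return v[ok], t[ok]


def sen_slope(values: Sequence[float], times: Sequence[float] | None = None) -> float:
    """Median of all pairwise slopes; NaN if fewer than 2 valid pairs.

    Pairs with identical times are skipped (they have no defined slope).
    """
    v, t = _clean(values, times)
    if v.size < 2:
        return float("nan")
    j, i = np.triu_indices(v.size, k=1)  # j < i here after swap below
    dt = t[i] - t[j]
    dv = v[i] - v[j]
    ok = dt != 0
    if not np.any(ok):
        return float("nan")
    return float(np.median(dv[ok] / dt[ok]))


def mk_test(values: Sequence[float]) -> tuple[int, float, float]:
    """Mann–Kendall S, Var(S) with tie correction, and continuity-corrected Z.

    Returns ``(nan, nan, nan)``-equivalent (S=0, varS=nan, Z=nan) for fewer
    than 4 valid values, where the test is undefined.
    """
    v, _ = _clean(values)
    n = v.size
    if n < 4:
        return 0, float("nan"), float("nan")
    j, i = np.triu_indices(n, k=1)
    S = int(np.sum(np.sign(v[i] - v[j])))
    _, counts = np.unique(v, return_counts=True)
    ties = counts[counts > 1]
    varS = (n * (n - 1) * (2 * n + 5)
            - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if varS <= 0:  # all values tied
        return S, float(varS), 0.0
    if S > 0:
        Z = (S - 1) / np.sqrt(varS)
    elif S < 0:
        Z = (S + 1) / np.sqrt(varS)
    else:
        Z = 0.0
    return S, float(varS), float(Z)


def classify_trend(beta: float, Z: float,
                   table: TrendClassTable = TrendClassTable()) -> int:
    """Signed trend class from (sign(beta), |Z|); 0 for beta == 0 / undefined."""
    if not np.isfinite(beta) or not np.isfinite(Z) or beta == 0:
        return 0
    t1, t2, t3 = table.thresholds
    a = abs(Z)
    if a >= t3:
        mag = 4
    elif a >= t2:
        mag = 3
    elif a >= t1:
        mag = 2
    else:
        mag = 1
    return mag if beta > 0 else -mag


def trend_raster(stack: RasterStack, min_epochs: int = 4,
                 table: TrendClassTable = TrendClassTable()
                 ) -> dict[str, RasterGrid]:
    """Per-pixel Sen slope, MK Z, trend class, and valid-epoch count.

    Pixels with fewer than ``min_epochs`` valid observations are masked in
    all outputs (``n_valid`` still reports the count).
    """
    if len(stack) < max(min_epochs, 4):
        raise RasterError(f"trend analysis needs >= {max(min_epochs, 4)} epochs, "
                          f"got {len(stack)}")
    cube = stack.as_cube()
    times = stack.times
    nt, rows, cols = cube.shape
    beta = np.full((rows, cols), np.nan)
    zmap = np.full((rows, cols), np.nan)
    nvalid = np.sum(np.isfinite(cube), axis=0).astype(float)

    # all-pairs index template reused across pixels
    flat = cube.reshape(nt, -1)
    valid = np.isfinite(flat)
    complete = valid.all(axis=0)

    # fast vectorized path for pixels observed at every epoch
    if np.any(complete):
        sub = flat[:, complete]
        j, i = np.triu_indices(nt, k=1)
        dt = times[i] - times[j]
        dv = sub[i] - sub[j]
        beta_c = np.median(dv / dt[:, None], axis=0)
        S_c = np.sum(np.sign(dv), axis=0)
        varS_c = np.empty(sub.shape[1])
        srt = np.sort(sub, axis=0)
        base = nt * (nt - 1) * (2 * nt + 5)
        # tie correction per pixel from sorted runs
        for k in range(sub.shape[1]):
            _, counts = np.unique(srt[:, k], return_counts=True)
            ties = counts[counts > 1]
            varS_c[k] = (base - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
        with np.errstate(invalid="ignore", divide="ignore"):
            Z_c = np.where(S_c > 0, (S_c - 1) / np.sqrt(varS_c),
                           np.where(S_c < 0, (S_c + 1) / np.sqrt(varS_c), 0.0))
        Z_c = np.where(varS_c <= 0, 0.0, Z_c)
        bflat = beta.reshape(-1)
        zflat = zmap.reshape(-1)
        bflat[complete] = beta_c
        zflat[complete] = Z_c

    # per-pixel path for gappy series
    gappy = np.flatnonzero(~complete & (valid.sum(axis=0) >= min_epochs))
    for idx in gappy:
        series = flat[:, idx]
        b = sen_slope(series, times)
        _, _, z = mk_test(series)
        beta.reshape(-1)[idx] = b
        zmap.reshape(-1)[idx] = z

    defined = np.isfinite(beta) & np.isfinite(zmap) & (nvalid >= min_epochs)
    beta[~defined] = np.nan
    zmap[~defined] = np.nan
    t1, t2, t3 = table.thresholds
    with np.errstate(invalid="ignore"):
        absz = np.abs(zmap)
        mag = 1.0 + (absz >= t1) + (absz >= t2) + (absz >= t3)
        cls = np.where(defined & (beta != 0), np.sign(beta) * mag, 0.0)
    tform, crs = stack.transform, stack.grids[0].crs_tag
    return {
        "beta": RasterGrid(beta, tform, ~defined, crs),
        "Z": RasterGrid(zmap, tform, ~defined, crs),
        "trend_class": RasterGrid(np.where(defined, cls, np.nan), tform,
                                  ~defined, crs),
        "n_valid": RasterGrid(nvalid, tform, np.zeros_like(defined), crs),
    }


def trend_class_areas(class_grid: RasterGrid) -> dict[int, float]:
    """Percentage of valid area in each signed trend class."""
    vals = class_grid.masked()
    ok = np.isfinite(vals)
    total = int(ok.sum())
    out: dict[int, float] = {}
    if total == 0:
        return out
    for code in sorted(TREND_CLASS_LABELS):
        cnt = int(np.sum(vals[ok] == code))
        if cnt:
            out[code] = 100.0 * cnt / total
    return out


def stack_std(stack: RasterStack) -> RasterGrid:
    """Per-pixel temporal standard deviation (population denominator n).

    Pixels with fewer than 2 valid epochs are masked.
    """
    cube = stack.as_cube()
    n = np.sum(np.isfinite(cube), axis=0)
    with np.errstate(all="ignore"):
        sd = np.nanstd(cube, axis=0, ddof=0)
    mask = n < 2
    sd = np.where(mask, np.nan, sd)
    return RasterGrid(sd, stack.transform, mask, stack.grids[0].crs_tag)
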