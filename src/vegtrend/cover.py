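"""Equal-interval NDVI cover classes, area statistics, and transfer matrices.

Vegetation cover is binned into five equal 0.2-wide NDVI classes — low
(< 0.2), medium-low [0.2, 0.4), medium [0.4, 0.6), medium-high [0.6, 0.8)
and high [0.8, 1.0].  Intervals are left-closed/right-open except the top
class, which is closed at 1.0; negative NDVI (water, bare soil) falls into
the low class unless masked upstream.  The transfer matrix cross-tabulates
class membership between two dates over the jointly valid area, so its row
sums are the date-1 class areas and its column sums the date-2 class areas.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .raster import RasterGrid, RasterError

__all__ = [
    "CoverScheme",
    "TransferMatrix",
    "classify_ndvi",
    "class_area_stats",
    "transfer_matrix",
]


@dataclasses.dataclass(frozen=True)
class CoverScheme:
    breaks: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)
    labels: tuple[str, ...] = ("low", "medium-low", "medium",
                               "medium-high", "high")

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.breaks) + 1:
            raise ValueError("need one more label than breaks")
        if not all(b1 < b2 for b1, b2 in zip(self.breaks, self.breaks[1:])):
            raise ValueError("breaks must be strictly increasing")

    @property
    def n_classes(self) -> int:
        return len(self.labels)


@dataclasses.dataclass
class TransferMatrix:
    """Area (km²) moving from each class at date 1 to each class at date 2."""

    matrix: np.ndarray
    labels: tuple[str, ...]
    total_area_km2: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.labels),
                            columns=list(self.labels))

    @property
    def row_areas(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    @property
    def col_areas(self) -> np.ndarray:
        return self.matrix.sum(axis=0)


def classify_ndvi(grid: RasterGrid, scheme: CoverScheme = CoverScheme()) -> RasterGrid:
    """Map NDVI to integer class codes 1..5 (low..high); NoData propagated."""
    vals = grid.masked()
    codes = np.full(vals.shape, np.nan)
    ok = np.isfinite(vals)
    # class k = 1 + number of breaks at or below the value
    codes[ok] = 1.0 + np.searchsorted(np.asarray(scheme.breaks), vals[ok],
                                      side="right")
    return RasterGrid(codes, grid.transform, ~ok, grid.crs_tag)


def class_area_stats(class_grid: RasterGrid,
                     scheme: CoverScheme = CoverScheme()) -> pd.DataFrame:
    """Per-class area in km² and percentage of the valid area."""
    vals = class_grid.masked()
    ok = np.isfinite(vals)
    n_valid = int(ok.sum())
    cell_area = class_grid.cell_area_km2
    if n_valid == 0:
        warnings.warn("class_area_stats: grid is fully masked")
    rows = []
    for k, label in enumerate(scheme.labels, start=1):
        cnt = int(np.sum(vals[ok] == k))
        rows.append({
            "class_code": k,
            "label": label,
            "pixels": cnt,
            "area_km2": cnt * cell_area,
            "percent": (100.0 * cnt / n_valid) if n_valid else 0.0,
        })
    return pd.DataFrame(rows)


def transfer_matrix(class_t1: RasterGrid, class_t2: RasterGrid,
                    scheme: CoverScheme = CoverScheme()) -> TransferMatrix:
    """Between-date class transition areas over the jointly valid pixels."""
    class_t1.require_same_geometry(class_t2, "transfer_matrix")
    a = class_t1.masked()
    b = class_t2.masked()
    both = np.isfinite(a) & np.isfinite(b)
    k = scheme.n_classes
    counts = np.zeros((k, k))
    ai = a[both].astype(int) - 1
    bi = b[both].astype(int) - 1
    if np.any((ai < 0) | (ai >= k) | (bi < 0) | (bi >= k)):
        raise RasterError("transfer_matrix: class codes outside 1..%d" % k)
    np.add.at(counts, (ai, bi), 1)
    cell_area = class_t1.cell_area_km2
    matrix = counts * cell_area
    return TransferMatrix(matrix=matrix, labels=scheme.labels,
                          total_area_km2=float(both.sum()) * cell_area)
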