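"""Grid data model, GeoTIFF I/O, harmonization, compositing, fishnet sampling.

The raster model is deliberately minimal: one 2-D band of float values with a
boolean NoData mask, a north-up affine geotransform (square cells, metres),
and an opaque CRS tag.  Row 0 is the northernmost row; cell (row, col) has its
centre at ``(x0 + (col + 0.5) dx, y0 - (row + 0.5) dx)`` where ``(x0, y0)`` is
the top-left corner of the grid.  Reprojection between coordinate systems is
out of scope: grids are compared by their transform and CRS tag and must
already live on the same (or nested) lattices.

GeoTIFF files are read and written through :mod:`tifffile`, using the standard
GeoTIFF TIFF tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory,
GeoAsciiParams) and the GDAL_NODATA convention.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "GridTransform",
    "RasterGrid",
    "RasterStack",
    "FishnetSample",
    "read_raster",
    "write_raster",
    "compute_ndvi",
    "max_value_composite",
    "harmonize",
    "make_fishnet",
    "sample_at_points",
]

# GeoTIFF / GDAL private TIFF tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GEO_ASCII_PARAMS = 34737
_TAG_GDAL_NODATA = 42113

_NODATA_VALUE = -9999.0


class RasterError(ValueError):
    """Contract violation on raster inputs (geometry mismatch, bad file...)."""


@dataclasses.dataclass(frozen=True)
class GridTransform:
    """North-up affine transform with square cells.

    Parameters
    ----------
    x0, y0
        Map coordinates (metres) of the **top-left corner** of the grid.
    cell_size
        Edge length of a (square) cell in metres; must be positive.
    """

    x0: float
    y0: float
    cell_size: float

    def __post_init__(self) -> None:
        if not (self.cell_size > 0):
            raise RasterError(f"cell size must be > 0, got {self.cell_size}")

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.x0 + (col + 0.5) * self.cell_size,
            self.y0 - (row + 0.5) * self.cell_size,
        )

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing map point (x, y)."""
        col = int(math.floor((x - self.x0) / self.cell_size))
        row = int(math.floor((self.y0 - y) / self.cell_size))
        return row, col

    def isclose(self, other: "GridTransform", tol: float = 1e-6) -> bool:
        return (
            abs(self.x0 - other.x0) <= tol
            and abs(self.y0 - other.y0) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )


@dataclasses.dataclass
class RasterGrid:
    """One 2-D georeferenced band with a NoData mask.

    ``values`` are finite wherever ``nodata_mask`` is False; masked cells may
    hold anything (they are written out as the NoData fill value).
    """

    values: np.ndarray
    transform: GridTransform
    nodata_mask: np.ndarray | None = None
    crs_tag: str = "local-metric"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise RasterError("grid values must be 2-D")
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise RasterError("mask shape must equal values shape")
        if not np.all(np.isfinite(self.values[~self.nodata_mask])):
            raise RasterError("unmasked cells must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area_km2(self) -> float:
        return (self.transform.cell_size / 1000.0) ** 2

    def masked(self) -> np.ndarray:
        """Values with NoData as NaN (a copy)."""
        out = self.values.astype(float).copy()
        out[self.nodata_mask] = np.nan
        return out

    def same_geometry(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and self.transform.isclose(other.transform)
            and self.crs_tag == other.crs_tag
        )

    def require_same_geometry(self, other: "RasterGrid", what: str) -> None:
        if not self.same_geometry(other):
            raise RasterError(f"{what}: grids are not co-registered "
                              f"(shape/transform/CRS mismatch)")


@dataclasses.dataclass
class RasterStack:
    """Time-ordered sequence of co-registered grids."""

    grids: list[RasterGrid]
    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.grids) != len(self.times):
            raise RasterError("one time coordinate per grid required")
        if len(self.grids) == 0:
            raise RasterError("empty stack")
        if not np.all(np.diff(self.times) > 0):
            raise RasterError("times must be strictly increasing")
        first = self.grids[0]
        for g in self.grids[1:]:
            first.require_same_geometry(g, "stack layer")

    def __len__(self) -> int:
        return len(self.grids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grids[0].shape

    @property
    def transform(self) -> GridTransform:
        return self.grids[0].transform

    def as_cube(self) -> np.ndarray:
        """(time, row, col) array with NoData as NaN."""
        return np.stack([g.masked() for g in self.grids], axis=0)


@dataclasses.dataclass
class FishnetSample:
    """Regular sample points and the values extracted at them.

    ``table`` has one row per point with columns ``point_id, x, y``, one
    column per sampled raster, and a boolean ``valid`` flag that is False for
    rows containing any NoData-sourced value.
    """

    points: list[tuple[float, float]]
    table: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# GeoTIFF I/O


def _geokey_directory(crs_tag: str) -> tuple[list[int], str]:
    """Minimal GeoKey directory: projected model, area pixels, citation."""
    ascii_params = crs_tag + "|"
    # header (version, rev, minor, count) then 4-short key entries
    keys = [1, 1, 0, 3]
    keys += [1024, 0, 1, 1]          # GTModelTypeGeoKey = projected
    keys += [1025, 0, 1, 1]          # GTRasterTypeGeoKey = PixelIsArea
    keys += [1026, _TAG_GEO_ASCII_PARAMS, len(ascii_params), 0]  # citation
    return keys, ascii_params


def write_raster(grid: RasterGrid, path: str | Path) -> Path:
    """Write a grid as a single-band float32 GeoTIFF.

    NoData cells are filled with −9999 and the GDAL_NODATA tag is set so that
    :func:`read_raster` (and GDAL-based tools) restore the mask.
    """
    path = Path(path)
    values = grid.values.astype(np.float32).copy()
    values[grid.nodata_mask] = _NODATA_VALUE
    t = grid.transform
    keys, ascii_params = _geokey_directory(grid.crs_tag)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (t.cell_size, t.cell_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.x0, t.y0, 0.0)),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(keys), tuple(keys)),
        (_TAG_GEO_ASCII_PARAMS, "s", len(ascii_params), ascii_params),
        (_TAG_GDAL_NODATA, "s", 0, str(_NODATA_VALUE)),
    ]
    tifffile.imwrite(path, values, extratags=extratags)
    return path


def read_raster(path: str | Path, band: int = 0) -> RasterGrid:
    """Read one band of a GeoTIFF into a :class:`RasterGrid`.

    Raises :class:`RasterError` if the file carries no georeferencing
    (ModelPixelScale + ModelTiepoint tags).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        if band >= len(tif.pages):
            raise RasterError(f"{path}: band {band} out of range "
                              f"({len(tif.pages)} bands)")
        page = tif.pages[band]
        values = page.asarray().astype(float)
        if values.ndim == 3:  # samples-per-pixel layout; take requested plane
            values = values[..., 0]
        tags = page.tags
        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise RasterError(f"{path}: missing georeferencing tags")
        scale = tags[_TAG_MODEL_PIXEL_SCALE].value
        tie = tags[_TAG_MODEL_TIEPOINT].value
        crs_tag = "unspecified"
        if _TAG_GEO_ASCII_PARAMS in tags:
            crs_tag = str(tags[_TAG_GEO_ASCII_PARAMS].value).rstrip("|\x00")
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            nodata = float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00 "))
    transform = GridTransform(x0=float(tie[3]), y0=float(tie[4]),
                              cell_size=float(scale[0]))
    mask = ~np.isfinite(values)
    if nodata is not None:
        mask |= values == nodata
    values = values.copy()
    values[mask] = np.nan
    return RasterGrid(values=values, transform=transform,
                      nodata_mask=mask, crs_tag=crs_tag)


# ---------------------------------------------------------------------------
# Band math and compositing


def compute_ndvi(red: RasterGrid, nir: RasterGrid) -> RasterGrid:
    """(NIR − Red)/(NIR + Red); cells with zero denominator are masked."""
    red.require_same_geometry(nir, "compute_ndvi")
    r, n = red.masked(), nir.masked()
    denom = n + r
    with np.errstate(invalid="ignore", divide="ignore"):
        ndvi = np.where(denom != 0, (n - r) / denom, np.nan)
    mask = ~np.isfinite(ndvi)
    ndvi = np.where(mask, np.nan, ndvi)
    return RasterGrid(ndvi, red.transform, mask, red.crs_tag)


def max_value_composite(stack: RasterStack) -> RasterGrid:
    """Per-pixel temporal maximum of unmasked values (MVC compositing).

    A pixel is masked in the composite only if it is masked at every epoch.
    """
    cube = stack.as_cube()
    with np.errstate(all="ignore"):
        comp = np.nanmax(cube, axis=0)
    mask = np.all(np.isnan(cube), axis=0)
    comp = np.where(mask, np.nan, comp)
    return RasterGrid(comp, stack.transform, mask, stack.grids[0].crs_tag)


# ---------------------------------------------------------------------------
# Harmonization (resampling / aggregation)


def _block_reduce(masked: np.ndarray, factor: int, how: str) -> np.ndarray:
    rows, cols = masked.shape
    out_r, out_c = rows // factor, cols // factor
    blocks = masked[: out_r * factor, : out_c * factor]
    blocks = blocks.reshape(out_r, factor, out_c, factor).swapaxes(1, 2)
    blocks = blocks.reshape(out_r, out_c, factor * factor)
    if how == "mean":
        with np.errstate(all="ignore"):
            return np.nanmean(blocks, axis=-1)
    # majority vote of unmasked categorical codes; ties -> smallest code
    out = np.full((out_r, out_c), np.nan)
    for i in range(out_r):
        for j in range(out_c):
            vals = blocks[i, j]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                continue
            codes, counts = np.unique(vals, return_counts=True)
            out[i, j] = codes[np.argmax(counts)]
    return out


def _bilinear(masked: np.ndarray, src: GridTransform, target: GridTransform,
              out_shape: tuple[int, int]) -> np.ndarray:
    rows, cols = out_shape
    jj = np.arange(cols)
    ii = np.arange(rows)
    x = target.x0 + (jj + 0.5) * target.cell_size
    y = target.y0 - (ii + 0.5) * target.cell_size
    # fractional source-cell-centre coordinates
    fc = (x - src.x0) / src.cell_size - 0.5
    fr = (src.y0 - y) / src.cell_size - 0.5
    fr2, fc2 = np.meshgrid(fr, fc, indexing="ij")
    r0 = np.clip(np.floor(fr2).astype(int), 0, masked.shape[0] - 1)
    c0 = np.clip(np.floor(fc2).astype(int), 0, masked.shape[1] - 1)
    r1 = np.clip(r0 + 1, 0, masked.shape[0] - 1)
    c1 = np.clip(c0 + 1, 0, masked.shape[1] - 1)
    wr = np.clip(fr2 - r0, 0.0, 1.0)
    wc = np.clip(fc2 - c0, 0.0, 1.0)
    v00 = masked[r0, c0]
    v01 = masked[r0, c1]
    v10 = masked[r1, c0]
    v11 = masked[r1, c1]
    top = v00 * (1 - wc) + v01 * wc
    bot = v10 * (1 - wc) + v11 * wc
    out = top * (1 - wr) + bot * wr
    # nearest-neighbour fallback where any corner is NoData
    bad = ~np.isfinite(out)
    if np.any(bad):
        rn = np.clip(np.rint(fr2).astype(int), 0, masked.shape[0] - 1)
        cn = np.clip(np.rint(fc2).astype(int), 0, masked.shape[1] - 1)
        out[bad] = masked[rn, cn][bad]
    return out


def _nearest(masked: np.ndarray, src: GridTransform, target: GridTransform,
             out_shape: tuple[int, int]) -> np.ndarray:
    rows, cols = out_shape
    jj = np.arange(cols)
    ii = np.arange(rows)
    x = target.x0 + (jj + 0.5) * target.cell_size
    y = target.y0 - (ii + 0.5) * target.cell_size
    c = np.floor((x - src.x0) / src.cell_size).astype(int)
    r = np.floor((src.y0 - y) / src.cell_size).astype(int)
    r2, c2 = np.meshgrid(r, c, indexing="ij")
    inb = (r2 >= 0) & (r2 < masked.shape[0]) & (c2 >= 0) & (c2 < masked.shape[1])
    out = np.full(out_shape, np.nan)
    out[inb] = masked[r2[inb], c2[inb]]
    return out


def harmonize(grid: RasterGrid, target: GridTransform,
              target_shape: tuple[int, int], mode: str = "continuous") -> RasterGrid:
    """Bring a grid onto a target geometry.

    Continuous data is aggregated by the unmasked-block mean when coarsening
    by an integer factor, and interpolated bilinearly when refining.
    Categorical data uses majority vote (coarsening) or nearest neighbour.
    NoData is never invented: an output cell is masked only when every
    contributing source cell is masked.
    """
    if mode not in ("continuous", "categorical"):
        raise RasterError(f"unknown harmonize mode {mode!r}")
    src = grid.transform
    # extent-overlap check
    src_x1 = src.x0 + grid.shape[1] * src.cell_size
    src_y1 = src.y0 - grid.shape[0] * src.cell_size
    tgt_x1 = target.x0 + target_shape[1] * target.cell_size
    tgt_y1 = target.y0 - target_shape[0] * target.cell_size
    if target.x0 >= src_x1 or tgt_x1 <= src.x0 or tgt_y1 >= src.y0 or target.y0 <= src_y1:
        raise RasterError("harmonize: source and target extents do not overlap")

    masked = grid.masked()
    ratio = target.cell_size / src.cell_size
    aligned = (abs(target.x0 - src.x0) < 1e-9 and abs(target.y0 - src.y0) < 1e-9)
    if aligned and ratio > 1 and abs(ratio - round(ratio)) < 1e-9:
        factor = int(round(ratio))
        how = "mean" if mode == "continuous" else "majority"
        out = _block_reduce(masked, factor, how)
        out = out[: target_shape[0], : target_shape[1]]
    elif mode == "continuous" and ratio < 1:
        out = _bilinear(masked, src, target, target_shape)
    else:
        out = _nearest(masked, src, target, target_shape)
    mask = ~np.isfinite(out)
    return RasterGrid(np.where(mask, np.nan, out), target, mask, grid.crs_tag)


# ---------------------------------------------------------------------------
# Fishnet sampling


def make_fishnet(extent: tuple[float, float, float, float],
                 spacing: float) -> FishnetSample:
    """Regular lattice of sample points inside an extent.

    Points sit at centres of a ``spacing``-sized square lattice anchored at
    the extent's lower-left corner ``(xmin, ymin)``; only centres strictly
    inside the extent are kept.
    """
    xmin, ymin, xmax, ymax = extent
    if not (spacing > 0):
        raise RasterError("fishnet spacing must be > 0")
    if xmax <= xmin or ymax <= ymin:
        raise RasterError("fishnet extent is empty")
    points: list[tuple[float, float]] = []
    ny = math.ceil((ymax - ymin) / spacing)
    nx = math.ceil((xmax - xmin) / spacing)
    for iy in range(ny):
        y = ymin + (iy + 0.5) * spacing
        if y >= ymax:
            continue
        for ix in range(nx):
            x = xmin + (ix + 0.5) * spacing
            if x >= xmax:
                continue
            points.append((x, y))
    return FishnetSample(points=points)


def sample_at_points(grids: Mapping[str, RasterGrid],
                     points: Sequence[tuple[float, float]]) -> FishnetSample:
    """Extract nearest-cell values from each named grid at each point.

    NoData and out-of-extent lookups yield NaN and clear the row's ``valid``
    flag.
    """
    rows = []
    for pid, (x, y) in enumerate(points):
        rec: dict[str, object] = {"point_id": pid, "x": x, "y": y}
        valid = True
        for name, grid in grids.items():
            r, c = grid.transform.index_of(x, y)
            if 0 <= r < grid.shape[0] and 0 <= c < grid.shape[1] and not grid.nodata_mask[r, c]:
                rec[name] = float(grid.values[r, c])
            else:
                rec[name] = np.nan
                valid = False
        rec["valid"] = valid
        rows.append(rec)
    table = pd.DataFrame(rows)
    return FishnetSample(points=list(points), table=table)
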