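"""Core raster containers and GeoTIFF I/O.

All maps in this package are single-band, north-up rasters on a common
metric grid: a :class:`CategoricalRaster` holds integer class codes, a
:class:`ContinuousRaster` holds a float surface (e.g. a DEM).  The grid is
described by a :class:`GridSpec` with pixel-center semantics — the cell at
(row, col) has its center at ``(origin_x + (col + 0.5) * dx,
origin_y - (row + 0.5) * dy)`` with the origin at the top-left corner and
rows increasing southward.

GeoTIFF files are read and written with :mod:`tifffile`, carrying the
standard georeferencing tags (ModelPixelScale, ModelTiepoint, GDAL_NODATA)
plus a free-form CRS tag compared for equality only; no reprojection is
performed anywhere — inputs are assumed pre-projected to one metric CRS.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

__all__ = [
    "GridSpec",
    "CategoricalRaster",
    "ContinuousRaster",
    "AlignmentReport",
    "read_categorical",
    "read_continuous",
    "write_raster",
    "assert_aligned",
    "resample_nearest",
]

# GeoTIFF / GDAL tag ids
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113
_TAG_DESCRIPTION = 270


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a north-up raster grid.

    ``origin_x, origin_y`` locate the *top-left corner* of the grid;
    ``dx, dy`` are strictly positive pixel sizes in meters (rows step
    southward by ``dy``).
    """

    origin_x: float
    origin_y: float
    dx: float
    dy: float
    nrows: int
    ncols: int
    crs: str = ""

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError(f"pixel size must be positive, got dx={self.dx}, dy={self.dy}")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and one column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def cell_center(self, row, col):
        """Map-space coordinates of cell centers (vectorized)."""
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.origin_x + (col + 0.5) * self.dx
        y = self.origin_y - (row + 0.5) * self.dy
        return x, y

    def locate(self, x, y):
        """Row/col of the cell containing map-space points (floor semantics)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.dx).astype(np.int64)
        row = np.floor((self.origin_y - y) / self.dy).astype(np.int64)
        return row, col

    def contains(self, x, y):
        row, col = self.locate(x, y)
        return (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) outer bounds."""
        return (
            self.origin_x,
            self.origin_y - self.nrows * self.dy,
            self.origin_x + self.ncols * self.dx,
            self.origin_y,
        )

    def geometry_equals(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.origin_x - other.origin_x) <= tol
            and abs(self.origin_y - other.origin_y) <= tol
            and abs(self.dx - other.dx) <= tol
            and abs(self.dy - other.dy) <= tol
        )


@dataclass
class CategoricalRaster:
    """Grid of integer class codes with an explicit legal code domain.

    Invariant: every non-nodata cell holds a code from ``class_domain``.
    """

    values: np.ndarray
    grid: GridSpec
    nodata: int
    class_domain: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            raise TypeError(f"categorical raster requires an integer dtype, got {self.values.dtype}")
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2D array")
        if self.values.shape != self.grid.shape:
            raise ValueError(f"values shape {self.values.shape} != grid shape {self.grid.shape}")
        self.class_domain = frozenset(int(c) for c in self.class_domain)
        self.validate_domain()

    def validate_domain(self) -> None:
        if not self.class_domain:
            return
        mask = self.values != self.nodata
        observed = np.unique(self.values[mask])
        bad = sorted(int(c) for c in observed if int(c) not in self.class_domain)
        if bad:
            counts = {c: int(np.sum(self.values == c)) for c in bad}
            raise ValueError(
                f"codes outside class domain {sorted(self.class_domain)}: "
                f"{bad} (cell counts {counts})"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of valid (non-nodata) cells."""
        return self.values != self.nodata

    def observed_codes(self) -> list[int]:
        return sorted(int(c) for c in np.unique(self.values[self.mask]))

    def with_values(self, values: np.ndarray, class_domain=None) -> "CategoricalRaster":
        return CategoricalRaster(
            values=values,
            grid=self.grid,
            nodata=self.nodata,
            class_domain=self.class_domain if class_domain is None else class_domain,
        )


@dataclass
class ContinuousRaster:
    """Float surface (DEM, slope, aspect) on a :class:`GridSpec`."""

    values: np.ndarray
    grid: GridSpec
    nodata: float = float("nan")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2D array")
        if self.values.shape != self.grid.shape:
            raise ValueError(f"values shape {self.values.shape} != grid shape {self.grid.shape}")
        valid = self.mask
        if not np.all(np.isfinite(self.values[valid])):
            raise ValueError("non-finite values present outside the nodata mask")

    @property
    def mask(self) -> np.ndarray:
        if np.isnan(self.nodata):
            return ~np.isnan(self.values)
        return self.values != self.nodata


@dataclass(frozen=True)
class AlignmentReport:
    """Outcome of an alignment check over a raster stack."""

    aligned: bool
    mismatch_pair: tuple[int, int] | None = None
    mismatch_property: str | None = None

    def __bool__(self) -> bool:
        return self.aligned

    def describe(self) -> str:
        if self.aligned:
            return "all rasters aligned"
        i, j = self.mismatch_pair
        return f"rasters {i} and {j} differ in {self.mismatch_property}"


def assert_aligned(rasters) -> AlignmentReport:
    """Check that all rasters share shape, geotransform, and CRS tag.

    Returns a report naming the first mismatching pair and property; raises
    only on an empty input list.
    """
    rasters = list(rasters)
    if not rasters:
        raise ValueError("alignment check requires at least one raster")
    ref = rasters[0].grid
    for j, r in enumerate(rasters[1:], start=1):
        g = r.grid
        if g.shape != ref.shape:
            return AlignmentReport(False, (0, j), "shape")
        if not ref.geometry_equals(g):
            return AlignmentReport(False, (0, j), "transform")
        if g.crs != ref.crs:
            return AlignmentReport(False, (0, j), "crs")
    return AlignmentReport(True)


def _geo_extratags(grid: GridSpec, nodata) -> list:
    return [
        (_TAG_PIXEL_SCALE, "d", 3, (float(grid.dx), float(grid.dy), 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(grid.origin_x), float(grid.origin_y), 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]


def write_raster(raster, path: str | os.PathLike) -> None:
    """Write a raster as a single-band GeoTIFF with georeferencing tags."""
    if isinstance(raster, CategoricalRaster):
        data = raster.values.astype(np.int32)
    else:
        data = raster.values.astype(np.float64)
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        description=f"CRS={raster.grid.crs}" if raster.grid.crs else None,
        extratags=_geo_extratags(raster.grid, raster.nodata),
    )


def _read_page(path):
    if not os.path.exists(path):
        raise FileNotFoundError(f"raster file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise ValueError(f"{path}: expected a single-band raster, found {len(tif.pages)} pages")
        page = tif.pages[0]
        values = page.asarray()
        tags = {t.code: t.value for t in page.tags.values()}
        tags[_TAG_DESCRIPTION] = page.description
    if values.ndim != 2:
        raise ValueError(f"{path}: expected a single band, got array of shape {values.shape}")
    scale = tags.get(_TAG_PIXEL_SCALE, (1.0, 1.0, 0.0))
    tie = tags.get(_TAG_TIEPOINT, (0.0, 0.0, 0.0, 0.0, 0.0, 0.0))
    nodata_s = tags.get(_TAG_GDAL_NODATA)
    crs = ""
    desc = tags.get(_TAG_DESCRIPTION, "")
    if isinstance(desc, str) and desc.startswith("CRS="):
        crs = desc[4:]
    grid = GridSpec(
        origin_x=float(tie[3]),
        origin_y=float(tie[4]),
        dx=float(scale[0]),
        dy=float(scale[1]),
        nrows=values.shape[0],
        ncols=values.shape[1],
        crs=crs,
    )
    return values, grid, nodata_s


def read_categorical(path, class_domain, nodata: int | None = None) -> CategoricalRaster:
    """Read an integer single-band GeoTIFF and validate its code domain.

    Raises if the band is float-valued or if any non-nodata cell carries a
    code outside ``class_domain`` (the error lists the offending codes and
    their cell counts).
    """
    values, grid, nodata_s = _read_page(path)
    if not np.issubdtype(values.dtype, np.integer):
        raise TypeError(f"{path}: categorical raster must have an integer band, got {values.dtype}")
    if nodata is None:
        nodata = int(float(nodata_s)) if nodata_s is not None else 0
    return CategoricalRaster(
        values=values.astype(np.int32),
        grid=grid,
        nodata=int(nodata),
        class_domain=frozenset(class_domain),
    )


def read_continuous(path, nodata: float | None = None) -> ContinuousRaster:
    """Read a float single-band GeoTIFF (e.g. a DEM)."""
    values, grid, nodata_s = _read_page(path)
    if nodata is None:
        nodata = float(nodata_s) if nodata_s is not None else float("nan")
    return ContinuousRaster(values=values.astype(np.float64), grid=grid, nodata=nodata)


def resample_nearest(source: ContinuousRaster, target: GridSpec) -> ContinuousRaster:
    """Nearest-neighbour resampling onto a target grid.

    Each output cell takes the value of the source cell whose center is
    nearest the output cell center; never introduces values absent from the
    source.  Raises when the source and target extents do not overlap.
    """
    sx0, sy0, sx1, sy1 = source.grid.extent
    tx0, ty0, tx1, ty1 = target.extent
    if tx1 <= sx0 or tx0 >= sx1 or ty1 <= sy0 or ty0 >= sy1:
        raise ValueError("source and target extents do not overlap")
    rows = np.arange(target.nrows)
    cols = np.arange(target.ncols)
    cx = target.origin_x + (cols + 0.5) * target.dx
    cy = target.origin_y - (rows + 0.5) * target.dy
    # nearest source center index = round(offset/step - 0.5), clamped to grid
    sc = np.rint((cx - source.grid.origin_x) / source.grid.dx - 0.5).astype(np.int64)
    sr = np.rint((source.grid.origin_y - cy) / source.grid.dy - 0.5).astype(np.int64)
    sc = np.clip(sc, 0, source.grid.ncols - 1)
    sr = np.clip(sr, 0, source.grid.nrows - 1)
    out = source.values[np.ix_(sr, sc)]
    return ContinuousRaster(values=out, grid=target, nodata=source.nodata)


def resample_nearest_categorical(source: CategoricalRaster, target: GridSpec) -> CategoricalRaster:
    """Nearest-neighbour resampling of a categorical raster (same rule)."""
    cont = ContinuousRaster(
        values=source.values.astype(np.float64), grid=source.grid, nodata=float(source.nodata)
    )
    out = resample_nearest(cont, target)
    return CategoricalRaster(
        values=out.values.astype(np.int32),
        grid=target,
        nodata=source.nodata,
        class_domain=source.class_domain,
    )
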