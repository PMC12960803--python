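"""Terrain derivatives and per-class terrain distributions.

Slope and aspect are derived from a DEM with the Horn 3x3 finite-difference
operator (the common GIS default): the east-west and north-south gradients
are weighted differences of the 8 neighbours, slope is
``arctan(sqrt(gx^2 + gy^2))`` in degrees, and aspect is the compass bearing
of the downslope direction, degrees clockwise from north.  Flat cells
(zero gradient) carry an undefined-aspect sentinel and are excluded from
aspect histograms rather than binned.  Border cells use edge replication.

:func:`class_terrain_summary` then characterises where a map places one
class (e.g. grassland) along elevation, slope and aspect gradients:
quantiles of elevation and slope plus an 8-sector aspect rose
(N = [337.5°, 22.5°), then NE, E, ... NW).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import CategoricalRaster, ContinuousRaster, assert_aligned

__all__ = ["ASPECT_SECTORS", "FLAT_ASPECT", "TerrainSummary", "slope_aspect", "class_terrain_summary"]

ASPECT_SECTORS = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")
FLAT_ASPECT = -1.0  # sentinel for undefined aspect on flat cells

_QUANTS = (0.05, 0.25, 0.5, 0.75, 0.95)


@dataclass
class TerrainSummary:
    """Elevation/slope quantiles and aspect rose of one class in one map."""

    dataset_name: str
    class_code: int
    n_cells: int
    elevation_quantiles: tuple  # (q05, q25, median, q75, q95) in m a.s.l.
    slope_quantiles: tuple  # same, in degrees
    aspect_histogram: dict  # sector -> cell count (flat cells excluded)
    empty: bool = False

    def to_frame(self) -> pd.DataFrame:
        row = {
            "dataset": self.dataset_name,
            "class": self.class_code,
            "n_cells": self.n_cells,
        }
        for q, v in zip(_QUANTS, self.elevation_quantiles):
            row[f"elev_q{int(q * 100):02d}"] = v
        for q, v in zip(_QUANTS, self.slope_quantiles):
            row[f"slope_q{int(q * 100):02d}"] = v
        for s in ASPECT_SECTORS:
            row[f"aspect_{s}"] = self.aspect_histogram.get(s, 0)
        return pd.DataFrame([row])


def slope_aspect(dem: ContinuousRaster) -> tuple[ContinuousRaster, ContinuousRaster]:
    """Horn 3x3 slope (degrees) and aspect (degrees clockwise from north).

    Requires a metric pixel size; raises when the grid step looks like
    geographic degrees.  Aspect is the downslope compass direction; flat
    cells get the :data:`FLAT_ASPECT` sentinel.
    """
    g = dem.grid
    if g.dx < 0.5 or g.dy < 0.5:
        raise ValueError(
            f"pixel size ({g.dx} x {g.dy}) looks like geographic degrees; "
            "slope/aspect require a metric CRS"
        )
    if g.nrows < 3 or g.ncols < 3:
        raise ValueError("slope/aspect need at least a 3x3 DEM")
    z = np.pad(dem.values, 1, mode="edge")
    # 3x3 neighbourhood, compass naming (top row of the array is north)
    nw, n_, ne = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    w_, e_ = z[1:-1, :-2], z[1:-1, 2:]
    sw, s_, se = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    gx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8.0 * g.dx)  # d z / d east
    gy = ((nw + 2 * n_ + ne) - (sw + 2 * s_ + se)) / (8.0 * g.dy)  # d z / d north
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    flat = (gx == 0) & (gy == 0)
    # downslope direction is -(gx, gy); bearing = atan2(east, north)
    aspect = np.degrees(np.arctan2(-gx, -gy)) % 360.0
    aspect[flat] = FLAT_ASPECT
    return (
        ContinuousRaster(values=slope, grid=g, nodata=float("nan")),
        ContinuousRaster(values=aspect, grid=g, nodata=float("nan")),
    )


def aspect_sector_index(aspect_deg: np.ndarray) -> np.ndarray:
    """Map aspect degrees to sector index 0..7 with N = [337.5, 22.5)."""
    return (np.floor((np.asarray(aspect_deg) + 22.5) / 45.0).astype(int)) % 8


def class_terrain_summary(
    map_raster: CategoricalRaster,
    class_code: int,
    dem: ContinuousRaster,
    slope: ContinuousRaster,
    aspect: ContinuousRaster,
    dataset_name: str = "",
) -> TerrainSummary:
    """Quantiles and aspect rose over exactly the cells mapped as ``class_code``.

    All rasters must share the grid (resample the DEM and its derivatives
    first).  Flat cells are excluded from the aspect histogram only; an
    absent class yields an empty, flagged summary.
    """
    rep = assert_aligned([map_raster])
    for r in (dem, slope, aspect):
        if not map_raster.grid.geometry_equals(r.grid):
            raise ValueError("terrain rasters must be aligned with the class map")
    sel = (map_raster.values == int(class_code)) & map_raster.mask
    n = int(sel.sum())
    if n == 0:
        return TerrainSummary(
            dataset_name=dataset_name,
            class_code=int(class_code),
            n_cells=0,
            elevation_quantiles=(np.nan,) * 5,
            slope_quantiles=(np.nan,) * 5,
            aspect_histogram={s: 0 for s in ASPECT_SECTORS},
            empty=True,
        )
    elev_q = tuple(float(v) for v in np.quantile(dem.values[sel], _QUANTS))
    slope_q = tuple(float(v) for v in np.quantile(slope.values[sel], _QUANTS))
    asp = aspect.values[sel]
    asp = asp[asp != FLAT_ASPECT]
    hist = {s: 0 for s in ASPECT_SECTORS}
    if asp.size:
        idx = aspect_sector_index(asp)
        for k, cnt in zip(*np.unique(idx, return_counts=True)):
            hist[ASPECT_SECTORS[int(k)]] = int(cnt)
    return TerrainSummary(
        dataset_name=dataset_name,
        class_code=int(class_code),
        n_cells=n,
        elevation_quantiles=elev_q,
        slope_quantiles=slope_q,
        aspect_histogram=hist,
    )
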