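"""Synthetic landscapes: truth maps, corrupted ensemble members, DEMs, points.

Every estimator and consensus rule in this package is testable against a
known ground truth because the generator controls the whole data-making
process:

* ``generate_truth`` draws a spatially autocorrelated categorical "truth"
  map: one smoothed Gaussian random field per class plus per-class offsets,
  the class with the largest field value winning each cell.  Offsets are
  calibrated iteratively so realized class proportions land within ±0.03 of
  the requested mix.
* ``corrupt`` derives an observed map from the truth by drawing each cell's
  class independently from a known row-stochastic confusion matrix — the
  exact error model assumed by the accuracy estimators.  Distinct seeds per
  dataset make ensemble members conditionally independent given the truth,
  the regime in which consensus rules provably help.
* ``generate_dem`` produces a smooth correlated surface with controllable
  relief amplitude.
* ``sample_labeled_points`` draws (optionally stratified) cell centers
  labeled with the truth, with an optional label-noise rate — a stand-in
  for interpreted validation points and survey-style training points.

The default ensemble configuration mimics the regime of current 10 m
land-cover products over mountain grasslands: 9 harmonized classes, a
grass-dominant mix, six members with per-class accuracies spanning
0.6–0.95, two of which systematically under-detect grassland.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import CategoricalRaster, ContinuousRaster, GridSpec
from .sampling import ValidationSample

__all__ = [
    "SyntheticConfig",
    "default_ensemble_confusions",
    "generate_truth",
    "corrupt",
    "generate_dem",
    "sample_labeled_points",
]


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic landscape in one place."""

    seed: int = 0
    shape: tuple = (256, 256)
    cell_size: float = 10.0
    n_classes: int = 9
    smoothness: float = 8.0  # correlation length of the truth field, in cells
    class_mix: tuple = ()  # target proportions; empty = equal shares
    confusions: tuple = ()  # per-dataset C x C row-stochastic matrices
    dem_relief: tuple = (1500.0, 20.0)  # (amplitude m, correlation length cells)
    dem_base: float = 500.0  # elevation of the lowest cell, m a.s.l.
    origin: tuple = (0.0, 0.0)
    crs: str = "synthetic-metric"

    def __post_init__(self) -> None:
        if not self.class_mix:
            self.class_mix = tuple([1.0 / self.n_classes] * self.n_classes)
        self.class_mix = tuple(float(p) for p in self.class_mix)
        if len(self.class_mix) != self.n_classes:
            raise ValueError("class_mix length must equal n_classes")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if self.smoothness <= 0 or self.dem_relief[1] <= 0:
            raise ValueError("correlation lengths must be positive")
        for m in self.confusions:
            m = np.asarray(m)
            if m.shape != (self.n_classes, self.n_classes):
                raise ValueError("each confusion matrix must be C x C")
            if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("confusion rows must sum to 1")

    @property
    def classes(self) -> tuple:
        return tuple(range(1, self.n_classes + 1))

    @property
    def grid(self) -> GridSpec:
        return GridSpec(
            origin_x=self.origin[0],
            origin_y=self.origin[1] + self.shape[0] * self.cell_size,
            dx=self.cell_size,
            dy=self.cell_size,
            nrows=self.shape[0],
            ncols=self.shape[1],
            crs=self.crs,
        )


def default_ensemble_confusions(n_datasets: int = 6, n_classes: int = 9, seed: int = 7):
    """Confusion matrices for the default 6-member, 9-class ensemble.

    Per-class diagonal accuracies span 0.6–0.95 with each member good at
    different classes; members 0 and 1 get low recall for class 5 (grass),
    leaking it mostly into crop/shrub — the "global products under-detect
    grassland" regime.  Off-diagonal mass prefers thematically adjacent
    classes.  Deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)
    mats = []
    for d in range(n_datasets):
        m = np.zeros((n_classes, n_classes))
        diag = rng.uniform(0.6, 0.95, size=n_classes)
        if d < 2 and n_classes >= 5:
            diag[4] = rng.uniform(0.55, 0.65)  # class 5 = grass, low recall
        for c in range(n_classes):
            m[c, c] = diag[c]
            off = rng.dirichlet(np.ones(n_classes - 1) * 0.6)
            m[c, np.arange(n_classes) != c] = (1.0 - diag[c]) * off
        mats.append(m)
    return tuple(mats)


def _correlated_field(shape, corr_len, rng) -> np.ndarray:
    """Zero-mean, unit-variance smoothed Gaussian field."""
    f = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(f, sigma=corr_len, mode="wrap")
    sd = f.std()
    if sd > 0:
        f = (f - f.mean()) / sd
    return f


def generate_truth(cfg: SyntheticConfig, tol: float = 0.03, max_iter: int = 400) -> CategoricalRaster:
    """Spatially autocorrelated truth map matching the target class mix.

    One correlated Gaussian field per class; per-class offsets are adapted
    until the realized proportions are within ``tol`` of ``class_mix`` (a
    class with target share 0 is excluded outright).  Deterministic under
    the config seed.
    """
    rng = np.random.default_rng(cfg.seed)
    mix = np.array(cfg.class_mix)
    active = mix > 0
    if active.sum() == 1:
        only = int(np.nonzero(active)[0][0]) + 1
        values = np.full(cfg.shape, only, dtype=np.int32)
        return CategoricalRaster(
            values=values, grid=cfg.grid, nodata=0, class_domain=frozenset(cfg.classes)
        )
    fields = np.stack(
        [_correlated_field(cfg.shape, cfg.smoothness, rng) for _ in range(cfg.n_classes)]
    )
    offsets = np.zeros(cfg.n_classes)
    offsets[~active] = -np.inf
    n_cells = fields[0].size
    labels = None
    for i in range(max_iter):
        labels = np.argmax(fields + offsets[:, None, None], axis=0)
        realized = np.bincount(labels.ravel(), minlength=cfg.n_classes) / n_cells
        err = realized - mix
        if np.abs(err[active]).max() <= tol * 0.5:
            break
        step = max(0.15, 0.8 * 0.99**i)
        offsets[active] -= step * err[active]
    realized = np.bincount(labels.ravel(), minlength=cfg.n_classes) / n_cells
    if np.abs((realized - mix)[active]).max() > tol:
        raise RuntimeError(
            "class-mix calibration failed; requested mix may be unreachable at "
            f"this smoothness (realized {np.round(realized, 3)})"
        )
    values = (labels + 1).astype(np.int32)
    return CategoricalRaster(
        values=values, grid=cfg.grid, nodata=0, class_domain=frozenset(cfg.classes)
    )


def corrupt(truth: CategoricalRaster, confusion, seed: int) -> CategoricalRaster:
    """Observed map: each cell's class drawn from its true class's confusion row.

    Independent per-cell draws (no spatial error correlation) — the error
    model under which point-based accuracy estimation is exact.
    """
    confusion = np.asarray(confusion, dtype=float)
    classes = sorted(truth.class_domain)
    c = len(classes)
    if confusion.shape != (c, c):
        raise ValueError(f"confusion must be {c}x{c} for this truth map")
    if not np.allclose(confusion.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("confusion rows must sum to 1")
    rng = np.random.default_rng(seed)
    u = rng.random(truth.values.shape)
    out = np.full(truth.values.shape, truth.nodata, dtype=np.int32)
    cum = np.cumsum(confusion, axis=1)
    code_arr = np.array(classes, dtype=np.int32)
    for k, code in enumerate(classes):
        sel = truth.values == code
        if not sel.any():
            continue
        draw = np.searchsorted(cum[k], u[sel], side="right")
        draw = np.minimum(draw, c - 1)
        out[sel] = code_arr[draw]
    return truth.with_values(out)


def corrupt_patchy(
    truth: CategoricalRaster, confusion, seed: int, blob_cells: float = 6.0
) -> CategoricalRaster:
    """Stress-test variant: errors hit contiguous blobs instead of single cells.

    Cells inside correlated error blobs are re-drawn from the confusion row
    conditional on error; the marginal per-class error rate matches the
    matrix only approximately.  For robustness experiments, not estimation.
    """
    confusion = np.asarray(confusion, dtype=float)
    classes = sorted(truth.class_domain)
    rng = np.random.default_rng(seed)
    blob = _correlated_field(truth.values.shape, blob_cells, rng)
    out = truth.values.copy()
    cum_all = np.cumsum(confusion, axis=1)
    code_arr = np.array(classes, dtype=np.int32)
    for k, code in enumerate(classes):
        p_err = 1.0 - confusion[k, k]
        thresh = np.quantile(blob, 1.0 - p_err) if 0 < p_err < 1 else np.inf
        sel = (truth.values == code) & (blob > thresh)
        if not sel.any():
            continue
        row = confusion[k].copy()
        row[k] = 0.0
        if row.sum() == 0:
            continue
        row = row / row.sum()
        draw = np.searchsorted(np.cumsum(row), rng.random(int(sel.sum())), side="right")
        draw = np.minimum(draw, len(classes) - 1)
        out[sel] = code_arr[draw]
    return truth.with_values(out)


def generate_dem(cfg: SyntheticConfig) -> ContinuousRaster:
    """Smooth correlated surface spanning ``dem_relief`` meters of relief."""
    rng = np.random.default_rng(cfg.seed + 104729)  # decoupled from the truth stream
    amplitude, corr_len = cfg.dem_relief
    if amplitude == 0:
        values = np.full(cfg.shape, cfg.dem_base)
    else:
        f = _correlated_field(cfg.shape, corr_len, rng)
        f01 = (f - f.min()) / (f.max() - f.min())
        values = cfg.dem_base + amplitude * f01
    return ContinuousRaster(values=values, grid=cfg.grid, nodata=float("nan"))


def sample_labeled_points(
    truth: CategoricalRaster,
    n: int,
    seed: int,
    strata: CategoricalRaster | None = None,
    counts: dict | None = None,
    noise_rate: float = 0.0,
) -> ValidationSample:
    """Cell centers labeled with the truth (plus optional label noise).

    With ``strata``/``counts`` the draw is stratified (without replacement
    per stratum); otherwise a simple random sample of ``n`` cells.  Labels
    land in ``label_1`` and, already adjudicated, in ``final_label``; the
    ``stratum`` column holds the stratum code (or 1).  Label noise flips a
    label to a uniformly different class with probability ``noise_rate``.
    """
    rng = np.random.default_rng(seed)
    grid = truth.grid
    classes = np.array(sorted(truth.class_domain), dtype=int)
    if strata is not None:
        if counts is None:
            raise ValueError("stratified draw requires per-stratum counts")
        rows_l, cols_l, strat_l = [], [], []
        for code in sorted(counts):
            k = int(counts[code])
            rr, cc = np.nonzero((strata.values == code) & truth.mask)
            if len(rr) < k:
                raise ValueError(f"stratum {code}: {len(rr)} cells available, {k} requested")
            pick = rng.choice(len(rr), size=k, replace=False)
            rows_l.append(rr[pick])
            cols_l.append(cc[pick])
            strat_l.append(np.full(k, code, dtype=int))
        rows = np.concatenate(rows_l)
        cols = np.concatenate(cols_l)
        strat = np.concatenate(strat_l)
    else:
        rr, cc = np.nonzero(truth.mask)
        if len(rr) < n:
            raise ValueError(f"requested {n} points but only {len(rr)} valid cells")
        pick = rng.choice(len(rr), size=n, replace=False)
        rows, cols = rr[pick], cc[pick]
        strat = np.ones(n, dtype=int)
    labels = truth.values[rows, cols].astype(int)
    if noise_rate > 0:
        flip = rng.random(labels.size) < noise_rate
        if flip.any():
            alt = rng.integers(0, len(classes) - 1, size=int(flip.sum()))
            cur_idx = np.searchsorted(classes, labels[flip])
            alt = alt + (alt >= cur_idx)  # uniform over the other classes
            labels[flip] = classes[alt]
    x, y = grid.cell_center(rows, cols)
    df = pd.DataFrame(
        {
            "x": x,
            "y": y,
            "stratum": strat,
            "label_1": labels,
            "final_label": labels,
        }
    )
    return ValidationSample(points=df, class_domain=frozenset(truth.class_domain))
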