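"""Design-based, area-weighted map accuracy estimation under stratified sampling.

Strata need not coincide with map classes: the stratification map is an
external product with its own codes.  Writing ``W_h`` for stratum h's area
proportion, ``n_h`` for its sample size and ``n_hij`` for the points in h
mapped as class i with reference class j, the cell proportions are estimated
as

    p_ij = sum_h  W_h * n_hij / n_h

and the accuracy measures follow from the estimated error matrix:

    OA   = sum_i p_ii
    UA_i = p_ii / p_i.          (row-conditional: commission view)
    PA_j = p_jj / p_.j          (column-conditional: omission view)
    F1_c = 2 * UA_c * PA_c / (UA_c + PA_c)

Standard errors are the classical design-based estimators for stratified
simple random sampling.  OA is a stratified mean of the per-point
correctness indicator y_u:

    V(OA) = sum_h W_h^2 * s_yh^2 / n_h ,   s_yh^2 the within-stratum sample
                                           variance of y

and UA/PA are ratio estimators R = X/Y of two indicator means, with the
linearised variance

    V(R) = (1 / Y^2) * sum_h W_h^2 / n_h * (s_xh^2 + R^2 s_yh^2 - 2 R s_xyh).

In the single-stratum case these collapse to the familiar simple-random
forms, e.g. SE(OA) = sqrt(OA (1-OA) / (n-1)).  A stratified bootstrap
(resampling points within strata) is provided as an independent cross-check
of the analytic formulas; it is used in the test suite, not in reports.

Classes absent from the sample yield *missing* (NaN) UA/PA/F1, never zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import CategoricalRaster
from .sampling import ValidationSample

__all__ = ["ErrorMatrix", "AccuracyReport", "cross_tabulate", "accuracy_report", "bootstrap_se"]

logger = logging.getLogger(__name__)


@dataclass
class ErrorMatrix:
    """Per-stratum map-by-reference cross-tabulation with area weights.

    ``counts[h]`` is a C x C integer array (rows = map class, columns =
    reference class) for stratum h; ``strata_weights[h]`` the stratum's area
    proportion W_h.
    """

    classes: tuple
    counts: dict[int, np.ndarray]
    strata_weights: dict[int, float]

    def __post_init__(self) -> None:
        self.classes = tuple(int(c) for c in self.classes)
        c = len(self.classes)
        for h, m in self.counts.items():
            m = np.asarray(m)
            if m.shape != (c, c):
                raise ValueError(f"stratum {h}: counts shape {m.shape} != ({c},{c})")
            if (m < 0).any():
                raise ValueError(f"stratum {h}: negative counts")
            self.counts[h] = m.astype(np.int64)
        w = sum(self.strata_weights[h] for h in self.counts)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"stratum weights over sampled strata must sum to 1, got {w}")

    @property
    def n_h(self) -> dict[int, int]:
        return {h: int(m.sum()) for h, m in self.counts.items()}

    @property
    def n_points(self) -> int:
        return sum(self.n_h.values())

    @property
    def proportions(self) -> np.ndarray:
        """Area-weighted cell proportions p_ij (sums to 1)."""
        c = len(self.classes)
        p = np.zeros((c, c))
        for h, m in self.counts.items():
            n_h = m.sum()
            if n_h > 0:
                p += self.strata_weights[h] * m / n_h
        return p

    @property
    def pooled_counts(self) -> np.ndarray:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.proportions, index=self.classes, columns=self.classes)


@dataclass
class AccuracyReport:
    """OA, per-class UA/PA/F1 and their standard errors for one map."""

    classes: tuple
    oa: float
    ua: dict[int, float]
    pa: dict[int, float]
    f1: dict[int, float]
    se_oa: float
    se_ua: dict[int, float]
    se_pa: dict[int, float]
    n_points: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.classes:
            rows.append(
                {
                    "class": c,
                    "ua": self.ua[c],
                    "pa": self.pa[c],
                    "f1": self.f1[c],
                    "se_ua": self.se_ua[c],
                    "se_pa": self.se_pa[c],
                }
            )
        df = pd.DataFrame(rows)
        df.attrs["oa"] = self.oa
        df.attrs["se_oa"] = self.se_oa
        return df


def cross_tabulate(
    map_raster: CategoricalRaster,
    sample: ValidationSample,
    strata_weights: dict[int, float],
    classes=None,
) -> ErrorMatrix:
    """Cross-tabulate map versus adjudicated reference labels per stratum.

    Points landing on nodata map cells (or outside the grid) are dropped
    with a logged count.  ``strata_weights`` gives each stratum's area
    proportion W_h; weights are renormalised over the strata actually
    present in the sample.
    """
    pts = sample.resolved()
    x = pts["x"].to_numpy()
    y = pts["y"].to_numpy()
    ref = pts["final_label"].to_numpy(dtype=int)
    strat = pts["stratum"].to_numpy(dtype=int)

    inside = map_raster.grid.contains(x, y)
    row, col = map_raster.grid.locate(x[inside], y[inside])
    mapped = map_raster.values[row, col]
    valid = mapped != map_raster.nodata
    n_dropped = int((~inside).sum() + (~valid).sum())
    if n_dropped:
        logger.warning("dropped %d validation points on nodata or outside the map", n_dropped)
    mapped = mapped[valid]
    ref = ref[inside][valid]
    strat = strat[inside][valid]

    if classes is None:
        domain = set(map_raster.class_domain) | set(sample.class_domain)
        if not domain:
            domain = set(np.unique(mapped)) | set(np.unique(ref))
        classes = tuple(sorted(domain))
    classes = tuple(int(c) for c in classes)
    idx = {c: k for k, c in enumerate(classes)}
    c = len(classes)

    counts: dict[int, np.ndarray] = {}
    for h in sorted(set(strat)):
        sel = strat == h
        m = np.zeros((c, c), dtype=np.int64)
        np.add.at(m, ([idx[v] for v in mapped[sel]], [idx[v] for v in ref[sel]]), 1)
        counts[h] = m

    present = sorted(counts)
    w_tot = sum(strata_weights[h] for h in present)
    weights = {h: strata_weights[h] / w_tot for h in present}
    return ErrorMatrix(classes=classes, counts=counts, strata_weights=weights)


def _stratum_indicator_stats(em: ErrorMatrix):
    """Per-stratum means/variances of the indicator variables used below."""
    stats = {}
    for h, m in em.counts.items():
        n_h = m.sum()
        stats[h] = (m, int(n_h))
    return stats


def _svar(p_bar: float, n: int) -> float:
    """Sample variance of a 0/1 indicator with mean p_bar over n points."""
    if n < 2:
        return 0.0
    return n / (n - 1.0) * p_bar * (1.0 - p_bar)


def _scov(pxy: float, px: float, py: float, n: int) -> float:
    """Sample covariance of two indicators from their joint/marginal means."""
    if n < 2:
        return 0.0
    return n / (n - 1.0) * (pxy - px * py)


def accuracy_report(em: ErrorMatrix) -> AccuracyReport:
    """Accuracy estimates with analytic design-based standard errors."""
    p = em.proportions
    classes = em.classes
    c = len(classes)
    row_tot = p.sum(axis=1)
    col_tot = p.sum(axis=0)
    diag = np.diag(p)

    oa = float(diag.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        ua = np.where(row_tot > 0, diag / row_tot, np.nan)
        pa = np.where(col_tot > 0, diag / col_tot, np.nan)
        f1 = np.where(
            np.nan_to_num(ua) + np.nan_to_num(pa) > 0,
            2 * ua * pa / (ua + pa),
            np.nan,
        )
        f1 = np.where(np.isnan(ua) | np.isnan(pa), np.nan, f1)

    # --- variances -------------------------------------------------------
    v_oa = 0.0
    v_ua = np.zeros(c)
    v_pa = np.zeros(c)
    for h, m in em.counts.items():
        n_h = int(m.sum())
        if n_h == 0:
            continue
        w2n = em.strata_weights[h] ** 2 / n_h
        frac = m / n_h
        # OA: mean of y_u = 1{map == ref}
        y_bar = float(np.trace(frac))
        v_oa += w2n * _svar(y_bar, n_h)
        for k in range(c):
            # UA_k: x = 1{map=k, ref=k}, y = 1{map=k}; x <= y so E[xy]=E[x]
            xb = float(frac[k, k])
            yb = float(frac[k, :].sum())
            v_ua[k] += w2n * (
                _svar(xb, n_h)
                + (ua[k] ** 2 if np.isfinite(ua[k]) else 0.0) * _svar(yb, n_h)
                - 2 * (ua[k] if np.isfinite(ua[k]) else 0.0) * _scov(xb, xb, yb, n_h)
            )
            # PA_k: y = 1{ref=k}
            yb = float(frac[:, k].sum())
            v_pa[k] += w2n * (
                _svar(xb, n_h)
                + (pa[k] ** 2 if np.isfinite(pa[k]) else 0.0) * _svar(yb, n_h)
                - 2 * (pa[k] if np.isfinite(pa[k]) else 0.0) * _scov(xb, xb, yb, n_h)
            )

    with np.errstate(divide="ignore", invalid="ignore"):
        se_ua = np.where(row_tot > 0, np.sqrt(np.maximum(v_ua, 0.0)) / row_tot, np.nan)
        se_pa = np.where(col_tot > 0, np.sqrt(np.maximum(v_pa, 0.0)) / col_tot, np.nan)

    return AccuracyReport(
        classes=classes,
        oa=oa,
        ua=dict(zip(classes, (float(v) for v in ua))),
        pa=dict(zip(classes, (float(v) for v in pa))),
        f1=dict(zip(classes, (float(v) for v in f1))),
        se_oa=float(np.sqrt(max(v_oa, 0.0))),
        se_ua=dict(zip(classes, (float(v) for v in se_ua))),
        se_pa=dict(zip(classes, (float(v) for v in se_pa))),
        n_points=em.n_points,
    )


def bootstrap_se(
    map_raster: CategoricalRaster,
    sample: ValidationSample,
    strata_weights: dict[int, float],
    B: int = 1000,
    seed: int = 0,
    classes=None,
):
    """Stratified bootstrap standard errors (resampling points within strata).

    An independent Monte-Carlo cross-check of the analytic formulas in
    :func:`accuracy_report`; B >= 100 replicates, identical replicate stream
    under a fixed seed.  Returns a dict with ``se_oa``, ``se_ua``, ``se_pa``.
    """
    if B < 100:
        raise ValueError("use at least 100 bootstrap replicates")
    rng = np.random.default_rng(seed)
    base = cross_tabulate(map_raster, sample, strata_weights, classes=classes)
    cls = base.classes
    pts = sample.resolved().reset_index(drop=True)
    strata = sorted(set(pts["stratum"].astype(int)))
    groups = {h: pts.index[pts["stratum"] == h].to_numpy() for h in strata}

    oas = np.empty(B)
    uas = np.full((B, len(cls)), np.nan)
    pas = np.full((B, len(cls)), np.nan)
    for b in range(B):
        take = np.concatenate(
            [rng.choice(groups[h], size=len(groups[h]), replace=True) for h in strata]
        )
        rep = ValidationSample(points=pts.loc[take], class_domain=sample.class_domain)
        r = accuracy_report(cross_tabulate(map_raster, rep, strata_weights, classes=cls))
        oas[b] = r.oa
        uas[b] = [r.ua[c] for c in cls]
        pas[b] = [r.pa[c] for c in cls]

    return {
        "se_oa": float(np.std(oas, ddof=1)),
        "se_ua": dict(zip(cls, np.nanstd(uas, axis=0, ddof=1))),
        "se_pa": dict(zip(cls, np.nanstd(pas, axis=0, ddof=1))),
    }
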