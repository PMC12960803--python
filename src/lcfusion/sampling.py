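"""Stratified validation sampling design and multi-interpreter adjudication.

The validation design follows the good-practices recipe for map accuracy
assessment: strata come from an external stratification map (independent of
the products under evaluation), the total sample size is chosen to hit a
target standard error on overall accuracy,

    n = ( sum_h W_h * S_h / SE_target )**2,      S_h = sqrt(UA_h * (1 - UA_h)),

where W_h is stratum h's area proportion and UA_h the accuracy expected
inside it.  Points are allocated proportionally to W_h and then raised to a
per-stratum floor (e.g. 70 points per class) so rare classes stay
estimable; the surplus is taken back from the largest allocations
proportionally.  Reference labels come from several interpreters per point
and are adjudicated by strict majority, with a confident-single-expert
override; points with no majority and no override stay unresolved and are
excluded downstream (with a logged count).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import CategoricalRaster

__all__ = [
    "StrataDesign",
    "SampleAllocation",
    "ValidationSample",
    "allocate_sample",
    "draw_points",
    "adjudicate",
]

logger = logging.getLogger(__name__)

UNRESOLVED = -1


@dataclass(frozen=True)
class StrataDesign:
    """Sampling strata with area weights and expected per-stratum accuracy."""

    strata: tuple  # of (stratum_code, weight W_h, expected UA_h)
    target_se_oa: float
    min_per_stratum: int = 70

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "strata", tuple((int(c), float(w), float(u)) for c, w, u in self.strata)
        )
        w_sum = sum(w for _, w, _ in self.strata)
        if abs(w_sum - 1.0) > 1e-9:
            raise ValueError(f"stratum weights must sum to 1, got {w_sum}")
        if any(not (0.0 < u < 1.0) for _, _, u in self.strata):
            raise ValueError("expected UA must lie strictly between 0 and 1")
        if any(w < 0 for _, w, _ in self.strata):
            raise ValueError("stratum weights must be nonnegative")
        if self.min_per_stratum < 1:
            raise ValueError("min_per_stratum must be at least 1")
        if self.target_se_oa <= 0:
            raise ValueError("target SE must be positive (SE=0 implies infinite n)")

    @property
    def codes(self) -> list[int]:
        return [c for c, _, _ in self.strata]


@dataclass
class SampleAllocation:
    """Pre-floor proportional allocation and the final floored allocation."""

    total_n: int
    proportional: dict[int, int]
    final: dict[int, int]

    @property
    def final_total(self) -> int:
        return sum(self.final.values())


def _largest_remainder_round(shares: np.ndarray, total: int) -> np.ndarray:
    """Round nonnegative shares summing to ``total`` to integers preserving the sum."""
    floor = np.floor(shares).astype(int)
    deficit = total - int(floor.sum())
    if deficit > 0:
        order = np.argsort(-(shares - floor))
        floor[order[:deficit]] += 1
    return floor


def allocate_sample(design: StrataDesign) -> SampleAllocation:
    """Compute per-stratum sample counts for the target SE on overall accuracy.

    Returns both the pre-floor proportional allocation and the final one.
    Guarantees: every final n_h >= min_per_stratum and the final total is at
    least the computed total n.
    """
    weights = np.array([w for _, w, _ in design.strata])
    s_h = np.array([math.sqrt(u * (1.0 - u)) for _, _, u in design.strata])
    total = int(math.ceil((float(weights @ s_h) / design.target_se_oa) ** 2))
    codes = design.codes
    prop = _largest_remainder_round(weights * total, total)

    floor = design.min_per_stratum
    final = np.maximum(prop, floor)
    surplus = int(final.sum()) - max(total, floor * len(codes))
    if surplus > 0:
        # take surplus back from the largest allocations, proportionally,
        # never dropping below the floor
        while surplus > 0:
            room = final - floor
            movable = room > 0
            if not movable.any():
                break
            take_share = final * movable / final[movable].sum()
            take = np.minimum(_largest_remainder_round(take_share * surplus, surplus), room)
            if take.sum() == 0:
                # fall back: peel one point at a time from the largest stratum
                i = int(np.argmax(np.where(movable, final, -1)))
                take = np.zeros_like(final)
                take[i] = 1
            final = final - take
            surplus = int(final.sum()) - max(total, floor * len(codes))
    return SampleAllocation(
        total_n=total,
        proportional=dict(zip(codes, (int(v) for v in prop))),
        final=dict(zip(codes, (int(v) for v in final))),
    )


@dataclass
class ValidationSample:
    """Labeled validation points backed by a DataFrame.

    Columns: ``x, y, stratum``, interpreter columns ``label_1..label_k``,
    ``override_rater``, ``override_label`` and, after adjudication,
    ``final_label`` (−1 marks unresolved points).
    """

    points: pd.DataFrame
    class_domain: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.points).reset_index(drop=True)
        for col in ("x", "y", "stratum"):
            if col not in df.columns:
                raise ValueError(f"validation sample missing column {col!r}")
        self.points = df
        self.class_domain = frozenset(int(c) for c in self.class_domain)

    @property
    def label_columns(self) -> list[str]:
        return [c for c in self.points.columns if c.startswith("label_")]

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def adjudicated(self) -> bool:
        return "final_label" in self.points.columns

    def resolved(self) -> pd.DataFrame:
        """Adjudicated points with a usable final label."""
        if not self.adjudicated:
            raise ValueError("sample not adjudicated yet")
        return self.points[self.points["final_label"] != UNRESOLVED]

    @classmethod
    def from_csv(cls, path, class_domain=()) -> "ValidationSample":
        return cls(points=pd.read_csv(path), class_domain=frozenset(class_domain))

    def to_csv(self, path) -> None:
        self.points.to_csv(path, index=False)


def draw_points(
    strat_map: CategoricalRaster, counts: dict[int, int], seed: int
) -> ValidationSample:
    """Simple random sample without replacement within each stratum.

    Points are placed at cell centers; the draw is reproducible under a
    fixed seed.  Raises when a stratum holds fewer eligible cells than
    requested.
    """
    rng = np.random.default_rng(seed)
    rows_out: list[np.ndarray] = []
    cols_out: list[np.ndarray] = []
    strata_out: list[np.ndarray] = []
    for code in sorted(counts):
        k = int(counts[code])
        rows, cols = np.nonzero(strat_map.values == code)
        if len(rows) < k:
            raise ValueError(
                f"stratum {code} has {len(rows)} eligible cells, {k} requested"
            )
        pick = rng.choice(len(rows), size=k, replace=False)
        rows_out.append(rows[pick])
        cols_out.append(cols[pick])
        strata_out.append(np.full(k, code, dtype=int))
    rows_all = np.concatenate(rows_out) if rows_out else np.array([], dtype=int)
    cols_all = np.concatenate(cols_out) if cols_out else np.array([], dtype=int)
    x, y = strat_map.grid.cell_center(rows_all, cols_all)
    df = pd.DataFrame(
        {
            "x": x,
            "y": y,
            "stratum": np.concatenate(strata_out) if strata_out else np.array([], dtype=int),
        }
    )
    return ValidationSample(points=df)


def adjudicate(sample: ValidationSample) -> ValidationSample:
    """Assign final labels: strict majority, else confident override, else unresolved.

    A strict majority means one label carried by more than half of the
    interpreter labels present for the point.  Unresolved points are kept in
    the table with ``final_label = -1`` and a logged count; downstream
    estimators drop them.
    """
    df = sample.points.copy()
    label_cols = sample.label_columns
    if not label_cols:
        raise ValueError("no interpreter label columns (label_1..label_k) present")
    labels = df[label_cols].to_numpy(dtype=float)
    final = np.full(len(df), UNRESOLVED, dtype=int)
    for i in range(len(df)):
        row = labels[i]
        row = row[~np.isnan(row)]
        if row.size == 0:
            continue
        vals, counts = np.unique(row.astype(int), return_counts=True)
        top = counts.max()
        if top * 2 > row.size:  # strict majority
            final[i] = int(vals[np.argmax(counts)])
    if "override_label" in df.columns:
        ov = df["override_label"].to_numpy(dtype=float)
        use = (final == UNRESOLVED) & ~np.isnan(ov)
        final[use] = ov[use].astype(int)
    df["final_label"] = final
    n_unresolved = int((final == UNRESOLVED).sum())
    if n_unresolved:
        logger.info("adjudication left %d of %d points unresolved", n_unresolved, len(df))
    return ValidationSample(points=df, class_domain=sample.class_domain)
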