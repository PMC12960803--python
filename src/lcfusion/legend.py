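"""Legend harmonisation: crosswalk remapping and multi-year mode aggregation.

Every source product carries its own class nomenclature; a
:class:`LegendCrosswalk` maps each source code onto the harmonized 9-class
scheme (LUCAS top level plus a snow/ice class):

    1=Built  2=Crop  3=Forest  4=Shrub  5=Grass  6=Bare  7=Water  8=Wet  9=Snow

Crosswalks are data (CSV with columns ``source_code, source_label,
target_code, target_label``), not code; the six crosswalks for the published
10 m products (CLC+ Backbone, Dynamic World, ELC10, ESA WorldCover, Esri
Land Cover, S2GLC) ship with the package under ``data/crosswalks``.
Many-to-one mappings are allowed (e.g. broadleaf and coniferous tree cover
both map to Forest); one-to-many is rejected at load time.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .raster import CategoricalRaster, assert_aligned

__all__ = [
    "HARMONIZED_CLASSES",
    "HARMONIZED_DOMAIN",
    "LegendCrosswalk",
    "load_packaged_crosswalk",
    "packaged_crosswalk_names",
    "apply_crosswalk",
    "temporal_mode",
]

HARMONIZED_CLASSES = {
    1: "Built",
    2: "Crop",
    3: "Forest",
    4: "Shrub",
    5: "Grass",
    6: "Bare",
    7: "Water",
    8: "Wet",
    9: "Snow",
}
HARMONIZED_DOMAIN = frozenset(HARMONIZED_CLASSES)


@dataclass
class LegendCrosswalk:
    """Mapping from one product's class codes to harmonized codes 1-9.

    ``default`` is either the string ``"error"`` (unmapped codes raise) or a
    harmonized code applied to any source code absent from the table.
    """

    source_name: str
    entries: pd.DataFrame  # columns: source_code, source_label, target_code, target_label
    default: int | str = "error"

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.entries)
        required = {"source_code", "source_label", "target_code"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"crosswalk missing columns: {sorted(missing)}")
        df = df.copy()
        df["source_code"] = df["source_code"].astype(int)
        df["target_code"] = df["target_code"].astype(int)
        if "target_label" not in df.columns:
            df["target_label"] = df["target_code"].map(HARMONIZED_CLASSES)
        bad_targets = sorted(set(df["target_code"]) - set(HARMONIZED_DOMAIN))
        if bad_targets:
            raise ValueError(f"target codes outside 1..9: {bad_targets}")
        dup = df.groupby("source_code")["target_code"].nunique()
        split = sorted(dup.index[dup > 1])
        if split:
            raise ValueError(
                f"source codes mapped to multiple targets (unsupported): {split}"
            )
        df = df.drop_duplicates(subset="source_code")
        if self.default != "error":
            d = int(self.default)
            if d not in HARMONIZED_DOMAIN:
                raise ValueError(f"default target code {d} outside 1..9")
            self.default = d
        self.entries = df.reset_index(drop=True)

    @property
    def mapping(self) -> dict[int, int]:
        return dict(zip(self.entries["source_code"], self.entries["target_code"]))

    @classmethod
    def from_csv(cls, path, source_name: str | None = None, default="error") -> "LegendCrosswalk":
        df = pd.read_csv(path)
        name = source_name if source_name is not None else str(path)
        return cls(source_name=name, entries=df, default=default)

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)


def packaged_crosswalk_names() -> list[str]:
    root = resources.files("lcfusion").joinpath("data/crosswalks")
    return sorted(p.name[:-4] for p in root.iterdir() if p.name.endswith(".csv"))


def load_packaged_crosswalk(name: str, default="error") -> LegendCrosswalk:
    """Load one of the shipped product crosswalks (e.g. ``"dw"``, ``"esa_wc"``)."""
    root = resources.files("lcfusion").joinpath("data/crosswalks")
    path = root.joinpath(f"{name}.csv")
    if not path.is_file():
        raise KeyError(f"no packaged crosswalk {name!r}; available: {packaged_crosswalk_names()}")
    with resources.as_file(path) as p:
        return LegendCrosswalk.from_csv(p, source_name=name, default=default)


def apply_crosswalk(r: CategoricalRaster, xw: LegendCrosswalk) -> CategoricalRaster:
    """Remap every non-nodata cell through the crosswalk; nodata is preserved.

    With ``default="error"`` any observed code absent from the table raises,
    listing the offending codes.
    """
    mapping = xw.mapping
    observed = set(r.observed_codes())
    unmapped = sorted(observed - set(mapping))
    if unmapped:
        if xw.default == "error":
            raise ValueError(
                f"crosswalk {xw.source_name!r} has no entry for observed codes {unmapped}"
            )
        for c in unmapped:
            mapping[c] = int(xw.default)
    # lookup-table remap; table spans the observed code range
    codes = np.array(sorted(mapping), dtype=np.int64)
    targets = np.array([mapping[c] for c in codes], dtype=np.int32)
    out = np.full(r.values.shape, r.nodata, dtype=np.int32)
    valid = r.mask
    idx = np.searchsorted(codes, r.values[valid])
    out[valid] = targets[idx]
    return CategoricalRaster(
        values=out, grid=r.grid, nodata=r.nodata, class_domain=HARMONIZED_DOMAIN
    )


def temporal_mode(stack: list[CategoricalRaster]) -> CategoricalRaster:
    """Per-pixel mode across a multi-year stack of aligned rasters.

    Each cell takes its most frequent non-nodata code across years; ties are
    broken by the lowest class code; a cell is nodata only when every year is
    nodata.  Used to stabilise products with strong seasonal variability
    (e.g. aggregating Dynamic World across years).
    """
    stack = list(stack)
    if len(stack) < 2:
        raise ValueError("temporal mode requires at least two rasters")
    rep = assert_aligned(stack)
    if not rep:
        raise ValueError(f"misaligned stack: {rep.describe()}")
    domain = stack[0].class_domain
    if any(r.class_domain != domain for r in stack):
        raise ValueError("all rasters in the stack must share a class domain")
    nodata = stack[0].nodata
    codes = sorted(domain) if domain else sorted(
        set().union(*(r.observed_codes() for r in stack))
    )
    arr = np.stack([r.values for r in stack])
    best = np.full(stack[0].values.shape, nodata, dtype=np.int32)
    best_count = np.zeros(stack[0].values.shape, dtype=np.int32)
    # ascending code order + strict '>' comparison implements lowest-code ties
    for c in codes:
        count = np.sum((arr == c), axis=0, dtype=np.int32)
        take = count > best_count
        best[take] = c
        best_count[take] = count[take]
    return CategoricalRaster(values=best, grid=stack[0].grid, nodata=nodata, class_domain=domain)
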