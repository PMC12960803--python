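"""YAML-configured end-to-end runs with a reproducibility manifest.

``run_pipeline`` wires the processing modules into the standard workflow —
harmonize → sample → assess → fit weights → consensus → terrain +
landscape metrics — driven entirely by a declarative YAML config, so no
stage reads anything the config does not name.  Every run writes a JSON
manifest recording the config hash, input file hashes, all seeds, the
package version and the rule switches in effect (tie-breaking,
connectivity, AccCo variant, edge handling); deterministic stages re-run
byte-identically from the same manifest inputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .accuracy import accuracy_report, cross_tabulate
from .consensus import consensus_accco, consensus_rf, consensus_wv, fit_weights
from .landmetrics import buffer_metrics
from .legend import LegendCrosswalk, apply_crosswalk, load_packaged_crosswalk, temporal_mode
from .raster import (
    read_categorical,
    read_continuous,
    resample_nearest,
    write_raster,
)
from .sampling import StrataDesign, ValidationSample, adjudicate, allocate_sample, draw_points
from .synthetic import (
    SyntheticConfig,
    corrupt,
    default_ensemble_confusions,
    generate_dem,
    generate_truth,
    sample_labeled_points,
)
from .terrain import class_terrain_summary, slope_aspect

__all__ = ["run_pipeline", "simulate_fixture", "RunManifest"]

DECISIONS_IN_EFFECT = {
    "mode_tie_rule": "lowest class code",
    "consensus_tie_rule": "most supporting datasets, then lowest class code",
    "patch_connectivity": 8,
    "accco_variant": "row",
    "edge_density_window_boundary": "excluded",
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


class RunManifest:
    """Accumulates provenance while a pipeline run executes."""

    def __init__(self, config: dict):
        cfg_bytes = json.dumps(config, sort_keys=True, default=str).encode()
        self.data = {
            "package": "lcfusion",
            "version": __version__,
            "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "config_sha256": hashlib.sha256(cfg_bytes).hexdigest(),
            "decisions_in_effect": dict(DECISIONS_IN_EFFECT),
            "inputs": {},
            "seeds": {},
            "stages": [],
        }

    def record_input(self, name: str, path) -> None:
        self.data["inputs"][name] = {"path": str(path), "sha256": _sha256(Path(path))}

    def record_seed(self, stage: str, seed: int) -> None:
        self.data["seeds"][stage] = int(seed)

    def record_stage(self, name: str, status: str = "ok") -> None:
        self.data["stages"].append({"stage": name, "status": status})

    def write(self, path) -> None:
        self.data["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=1)


def simulate_fixture(outdir, seed: int = 0, shape=(256, 256), n_datasets: int = 6) -> dict:
    """Write the default synthetic fixture set (truth, members, DEM, points).

    Returns the manifest dict (also written to ``manifest.json``); GeoTIFFs
    plus a validation/training CSV, everything reproducible from the
    recorded seeds.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mix = (0.06, 0.16, 0.26, 0.08, 0.25, 0.07, 0.04, 0.04, 0.04)  # grass-heavy mountain mix
    cfg = SyntheticConfig(seed=seed, shape=tuple(shape), class_mix=mix)
    confs = default_ensemble_confusions(n_datasets=n_datasets, n_classes=cfg.n_classes)
    truth = generate_truth(cfg)
    write_raster(truth, outdir / "truth.tif")
    members = []
    for d, m in enumerate(confs):
        obs = corrupt(truth, m, seed=seed * 1000 + d + 1)
        write_raster(obs, outdir / f"member_{d}.tif")
        members.append(f"member_{d}.tif")
    dem = generate_dem(cfg)
    write_raster(dem, outdir / "dem.tif")
    n_points = min(3000, truth.values.size // 2)
    pts = sample_labeled_points(truth, n=n_points, seed=seed + 555)
    pts.to_csv(outdir / "points.csv")
    manifest = {
        "seed": seed,
        "shape": list(shape),
        "class_mix": list(mix),
        "n_datasets": n_datasets,
        "confusions": [np.asarray(c).tolist() for c in confs],
        "files": {"truth": "truth.tif", "members": members, "dem": "dem.tif", "points": "points.csv"},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _load_crosswalk(spec) -> LegendCrosswalk:
    if isinstance(spec, str) and not spec.endswith(".csv"):
        return load_packaged_crosswalk(spec)
    return LegendCrosswalk.from_csv(spec)


def _require(config: dict, key: str, stage: str):
    if key not in config:
        raise KeyError(f"config for stage {stage!r} is missing required key {key!r}")
    return config[key]


def run_pipeline(config_path, outdir=None) -> Path:
    """Execute the stages named in a YAML config, in dependency order.

    Supported stages (any subset): ``simulate``, ``harmonize``,
    ``temporal_mode``, ``sample``, ``assess``, ``fit_weights``,
    ``consensus``, ``terrain``, ``landmetrics``.  Each stage's outputs land
    in the output directory; a failure is re-raised with the stage name
    after the manifest notes the partial state.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError("config must be a YAML mapping")
    out = Path(outdir if outdir is not None else _require(config, "outdir", "run"))
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config)
    domain = frozenset(range(1, 10))

    maps = {}
    sample = None
    strata_weights = None
    model = None

    def load_map(path):
        p = Path(path)
        if not p.is_absolute():
            p = config_path.parent / p
        manifest.record_input(p.name, p)
        return read_categorical(p, class_domain=domain)

    try:
        if "simulate" in config:
            sc = config["simulate"]
            seed = int(sc.get("seed", 0))
            manifest.record_seed("simulate", seed)
            fx = simulate_fixture(out / "fixtures", seed=seed, shape=tuple(sc.get("shape", (256, 256))))
            for i, name in enumerate(fx["files"]["members"]):
                maps[f"member_{i}"] = read_categorical(out / "fixtures" / name, class_domain=domain)
            manifest.record_stage("simulate")

        if "harmonize" in config:
            for item in config["harmonize"]:
                r = load_map(_require(item, "map", "harmonize"))
                xw = _load_crosswalk(_require(item, "crosswalk", "harmonize"))
                name = item.get("name", Path(item["map"]).stem)
                # source maps may use arbitrary product codes; re-read without domain
                r = read_categorical(
                    Path(item["map"]) if Path(item["map"]).is_absolute() else config_path.parent / item["map"],
                    class_domain=xw.mapping.keys(),
                )
                harmonized = apply_crosswalk(r, xw)
                write_raster(harmonized, out / f"{name}_harmonized.tif")
                maps[name] = harmonized
            manifest.record_stage("harmonize")

        if "temporal_mode" in config:
            tm = config["temporal_mode"]
            stack = [load_map(p) for p in _require(tm, "maps", "temporal_mode")]
            mode = temporal_mode(stack)
            write_raster(mode, out / f"{tm.get('name', 'mode')}.tif")
            maps[tm.get("name", "mode")] = mode
            manifest.record_stage("temporal_mode")

        if "maps" in config:
            for item in config["maps"]:
                maps[item["name"]] = load_map(item["path"])

        if "sample" in config:
            sc = config["sample"]
            strata = load_map(_require(sc, "strata_map", "sample"))
            design = StrataDesign(
                strata=[tuple(s) for s in _require(sc, "strata", "sample")],
                target_se_oa=float(sc.get("target_se_oa", 0.01)),
                min_per_stratum=int(sc.get("min_per_stratum", 70)),
            )
            alloc = allocate_sample(design)
            seed = int(sc.get("seed", 0))
            manifest.record_seed("sample", seed)
            drawn = draw_points(strata, alloc.final, seed=seed)
            drawn.to_csv(out / "sample_points.csv")
            strata_weights = {c: w for c, w, _ in design.strata}
            manifest.record_stage("sample")

        if "reference" in config:
            rc = config["reference"]
            p = Path(rc["points"]) if Path(rc["points"]).is_absolute() else config_path.parent / rc["points"]
            manifest.record_input(p.name, p)
            sample = ValidationSample.from_csv(p, class_domain=domain)
            if "final_label" not in sample.points.columns:
                sample = adjudicate(sample)
            strata_weights = {int(k): float(v) for k, v in rc.get("strata_weights", {}).items()} or strata_weights

        if strata_weights is None and sample is not None:
            codes = sorted(set(sample.points["stratum"].astype(int)))
            strata_weights = {c: 1.0 / len(codes) for c in codes}

        if "assess" in config:
            rows = []
            for name, r in maps.items():
                rep = accuracy_report(cross_tabulate(r, sample, strata_weights))
                df = rep.to_frame()
                df.insert(0, "dataset", name)
                df["oa"] = rep.oa
                df["se_oa"] = rep.se_oa
                rows.append(df)
            pd.concat(rows).to_csv(out / "accuracy.csv", index=False)
            manifest.record_stage("assess")

        if "fit_weights" in config or "consensus" in config:
            names = sorted(maps)
            model = fit_weights(
                [maps[n] for n in names], sample, strata_weights, dataset_names=names
            )
            model.to_json(out / "consensus_model.json")
            manifest.record_stage("fit_weights")

        if "consensus" in config:
            cc = config["consensus"]
            rules = [r.lower() for r in cc.get("rules", ["wv", "accco", "rf"])]
            names = sorted(maps)
            stack = [maps[n] for n in names]
            if "wv" in rules:
                write_raster(consensus_wv(stack, model), out / "consensus_wv.tif")
            if "accco" in rules:
                write_raster(
                    consensus_accco(stack, model, variant=cc.get("accco_variant", "row")),
                    out / "consensus_accco.tif",
                )
            if "rf" in rules:
                seed = int(cc.get("seed", 0))
                manifest.record_seed("consensus_rf", seed)
                tr_path = cc.get("training")
                if tr_path:
                    p = Path(tr_path) if Path(tr_path).is_absolute() else config_path.parent / tr_path
                    training = ValidationSample.from_csv(p, class_domain=domain)
                else:
                    training = sample
                write_raster(
                    consensus_rf(stack, model, training, seed=seed,
                                 n_trees=int(cc.get("n_trees", 500))),
                    out / "consensus_rf.tif",
                )
            manifest.record_stage("consensus")

        if "terrain" in config:
            tc = config["terrain"]
            p = Path(tc["dem"]) if Path(tc["dem"]).is_absolute() else config_path.parent / tc["dem"]
            manifest.record_input(p.name, p)
            dem = read_continuous(p)
            any_map = next(iter(maps.values()))
            if not dem.grid.geometry_equals(any_map.grid):
                dem = resample_nearest(dem, any_map.grid)
            slope, aspect = slope_aspect(dem)
            cls = int(tc.get("class", 5))
            frames = [
                class_terrain_summary(r, cls, dem, slope, aspect, dataset_name=n).to_frame()
                for n, r in maps.items()
            ]
            pd.concat(frames).to_csv(out / "terrain_summary.csv", index=False)
            manifest.record_stage("terrain")

        if "landmetrics" in config:
            lc = config["landmetrics"]
            cls = int(lc.get("class", 5))
            frames = []
            for n, r in maps.items():
                df = buffer_metrics(
                    r,
                    cls,
                    spacing=float(lc.get("spacing", 5000.0)),
                    radius=float(lc.get("radius", 2500.0)),
                )
                df.insert(0, "dataset", n)
                frames.append(df)
            pd.concat(frames).to_csv(out / "landmetrics.csv", index=False)
            manifest.record_stage("landmetrics")
    except Exception as exc:  # annotate with the failing stage, keep partial outputs
        manifest.record_stage(type(exc).__name__, status=f"failed: {exc}")
        manifest.write(out / "manifest.json")
        raise
    manifest.write(out / "manifest.json")
    return out
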