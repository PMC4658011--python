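"""End-to-end orchestration with a reproducibility manifest.

A run is described by a JSON-serializable config.  Stages execute in order —
simulate → segment → kinetics → features → classify / cluster — and any stage
can be skipped by supplying its product as an input (e.g. starting from a
feature CSV).  Every run writes a manifest recording the config hash, seeds,
input digests, per-stage timings, and a SHA-256 digest of every output file,
so identical configs reproduce identical artifacts for deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

from . import __version__
from .errors import RadbpeError
from . import io as rio
from .clustering import cluster_bpe
from .kinetics import compute_maps
from .modeling import CvConfig, compare_models, run_nested_cv, selection_frequency
from .phantom import PhantomSpec, generate_dce_phantom
from .segmentation import breast_density, segment_all
from .tables import FeatureTableSpec, BlockSpec, generate_feature_table
from .texture import extract_compartment_features


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()


def table_spec_from_config(cfg: dict, seed: int | None = None) -> FeatureTableSpec:
    cfg = dict(cfg)
    if seed is not None:
        cfg["seed"] = seed
    if "blocks" in cfg:
        cfg["blocks"] = {k: BlockSpec(**v) for k, v in cfg["blocks"].items()}
    return FeatureTableSpec(**cfg)


def phantom_spec_from_config(cfg: dict, seed: int | None = None) -> PhantomSpec:
    cfg = dict(cfg)
    if seed is not None:
        cfg["seed"] = seed
    for key in ("grid_shape", "voxel_spacing", "breast_radii", "breast_center",
                "tumor_center", "times"):
        if key in cfg and cfg[key] is not None:
            cfg[key] = tuple(cfg[key])
    return PhantomSpec(**cfg)


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute the configured stages and return the run manifest.

    Raises :class:`RadbpeError` with a stage-tagged message on schema
    violations, missing inputs, or stage failures.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get("stages", {})
    inputs = config.get("inputs", {})
    manifest = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": seed,
        "stages": {},
        "inputs": {},
        "outputs": {},
        "skipped": [],
    }
    for name, path in inputs.items():
        p = Path(path)
        if not p.exists():
            raise RadbpeError(f"[inputs] missing input: {path}")
        manifest["inputs"][name] = _sha256(p)

    def record(stage: str, started: float, outputs: dict) -> None:
        manifest["stages"][stage] = {"seconds": round(time.perf_counter() - started, 3)}
        for key, path in outputs.items():
            manifest["outputs"][key] = {"path": str(path), "sha256": _sha256(Path(path))}

    table = None
    volume = masks = truth = None

    if "table_csv" in inputs:
        table = rio.read_feature_csv(inputs["table_csv"])
        manifest["skipped"] += ["simulate", "segment", "kinetics", "features"]
    elif "simulate" in stages:
        t0 = time.perf_counter()
        sim = stages["simulate"]
        kind = sim.get("kind")
        if kind == "table":
            table = generate_feature_table(table_spec_from_config(sim.get("spec", {}), seed))
            path = out / "table.csv"
            rio.write_feature_csv(table, path)
            record("simulate", t0, {"table": path})
            manifest["skipped"] += ["segment", "kinetics", "features"]
        elif kind == "phantom":
            spec = phantom_spec_from_config(sim.get("spec", {}), seed)
            volume, masks, truth = generate_dce_phantom(spec)
            vol_path = out / "volume.nii"
            rio.write_volume(volume, vol_path)
            truth_path = out / "ground_truth.json"
            rio.write_ground_truth(truth, truth_path)
            outputs = {"volume": vol_path, "ground_truth": truth_path}
            for cname in ("breast", "tumor", "parenchyma", "adipose"):
                p = out / f"true_{cname}.nii"
                rio.write_mask(getattr(masks, cname), spec.voxel_spacing, p)
                outputs[f"true_{cname}"] = p
            record("simulate", t0, outputs)
        else:
            raise RadbpeError("[simulate] kind must be 'phantom' or 'table'")

    if table is None and volume is not None and "segment" in stages:
        t0 = time.perf_counter()
        seg = stages["segment"]
        try:
            seg_masks = segment_all(
                volume,
                seed_point=tuple(seg["seed_point"]),
                intensity_band=tuple(seg["intensity_band"]),
                chest_wall=seg.get("chest_wall"),
                fcm_seed=seed,
            )
        except KeyError as e:
            raise RadbpeError(f"[segment] missing config key: {e}") from e
        outputs = {}
        for cname in ("breast", "tumor", "parenchyma", "adipose"):
            p = out / f"{cname}.nii"
            rio.write_mask(getattr(seg_masks, cname), volume.spacing, p)
            outputs[cname] = p
        density = breast_density(seg_masks)
        (out / "density.json").write_text(json.dumps({"breast_density_percent": density}))
        outputs["density"] = out / "density.json"
        record("segment", t0, outputs)

        t0 = time.perf_counter()
        maps = compute_maps(volume, seg_masks.breast)
        outputs = {}
        for mname, fname in (("rate in", "rate_in"), ("PE", "pe"), ("SER", "ser")):
            p = out / f"{fname}.nii"
            rio.write_map(maps.maps[mname], maps.valid[mname], volume.spacing, p)
            outputs[fname] = p
        record("kinetics", t0, outputs)

        t0 = time.perf_counter()
        record_feats = {}
        record_feats.update(extract_compartment_features(maps, seg_masks.tumor, "tumor"))
        record_feats.update(
            extract_compartment_features(maps, seg_masks.parenchyma, "parenchyma")
        )
        record_feats["breast density"] = density
        p = out / "features.json"
        p.write_text(json.dumps(record_feats, indent=2))
        record("features", t0, {"features": p})

    if table is not None and "classify" in stages:
        t0 = time.perf_counter()
        clf = stages["classify"]
        task = clf.get("task", "tn_vs_others")
        task_table = table.task_subset(task)
        cv_config = CvConfig(**{**clf.get("config", {}), "seed": seed})
        scopes = clf.get("scopes", ["tumor", "tumor+bpe"])
        results = {}
        outputs = {}
        for scope in scopes:
            res = run_nested_cv(task_table, cv_config, scope)
            results[scope] = res
            summary = res.summary()
            freq = selection_frequency(res, floor=clf.get("frequency_floor", 50.0))
            stem = scope.replace("+", "_")
            metrics_path = out / f"{task}_{stem}_metrics.json"
            metrics_path.write_text(json.dumps(summary, indent=2))
            freq_path = out / f"{task}_{stem}_selection.tsv"
            freq.to_csv(freq_path, sep="\t", header=["percent_of_folds"])
            outputs[f"{task}:{scope}:metrics"] = metrics_path
            outputs[f"{task}:{scope}:selection"] = freq_path
        if len(scopes) == 2:
            p_vals = compare_models(results[scopes[0]], results[scopes[1]])
            cmp_path = out / f"{task}_comparison.json"
            cmp_path.write_text(json.dumps(p_vals, indent=2))
            outputs[f"{task}:comparison"] = cmp_path
        record("classify", t0, outputs)

    if table is not None and "cluster" in stages:
        t0 = time.perf_counter()
        ccfg = stages["cluster"]
        result, composition = cluster_bpe(
            table, restarts=ccfg.get("restarts", 50), seed=seed
        )
        assign_path = out / "cluster_assignments.csv"
        with open(assign_path, "w") as fh:
            fh.write("case_id,partition\n")
            for cid, a in zip(table.case_ids, result.assignments):
                fh.write(f"{cid},{a}\n")
        comp_path = out / "cluster_composition.json"
        comp_path.write_text(json.dumps(composition, indent=2))
        record("cluster", t0, {"assignments": assign_path, "composition": comp_path})

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
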