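"""End-to-end pipeline orchestration from a single config file.

Stages run in order — simulate, train, segment-srs, segment-he, count,
evaluate — skipping any stage whose outputs already exist unless forced.
One top-level seed fans out to per-stage seeds by fixed offsets, so two
runs with the same config produce byte-identical counts and metrics
JSON.  A manifest naming the config snapshot, seeds, stage timings and
outputs is written even when a stage fails.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import __version__, metrics, tiling
from .counting import CountResult, count_from_mask
from .hekmeans import HEKMeansSegmenter
from .imaging import CalibratedImage, RunConfig, load_image, load_instance_map, save_image, save_mask
from .simulate import SceneSpec, generate_paired_he, generate_srs_scene, semantic_mask
from .unet import UNet, UNetSegmenter

log = logging.getLogger("srscount")

# fixed per-stage seed offsets derived from the config seed
_SEED_SCENE = 0
_SEED_TRAIN = 100
_SEED_HE = 200

_TOP_KEYS = {"seed", "outdir", "resolution_um_per_px", "simulate", "scene",
             "model", "run", "srs_image", "he_image", "train_mask", "plots"}


def load_pipeline_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = sorted(set(cfg) - _TOP_KEYS)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    if "resolution_um_per_px" not in cfg:
        raise ValueError("config must set resolution_um_per_px")
    cfg.setdefault("seed", 0)
    cfg.setdefault("outdir", "srscount_out")
    cfg.setdefault("simulate", False)
    cfg.setdefault("scene", {})
    cfg.setdefault("model", {})
    cfg.setdefault("run", {})
    run_kwargs = dict(cfg["run"])
    run_kwargs.setdefault("seed", cfg["seed"])
    cfg["run"] = dataclasses.asdict(RunConfig.from_mapping(run_kwargs))
    return cfg


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _count_summary(r: CountResult) -> dict:
    return {
        "n_instances": r.n_instances,
        "n_cells": r.n_cells,
        "fence_um2": r.fence_um2,
        "mean_cell_area_um2": r.mean_cell_area_um2,
        "n_excluded": len(r.excluded_regions),
        "excluded_reasons": sorted({reason for _, reason in r.excluded_regions}),
    }


def run_pipeline(config_path: str | Path, force: bool = False) -> dict:
    """Execute the full pipeline; returns the manifest dict."""
    cfg = load_pipeline_config(config_path)
    out = Path(cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    res = float(cfg["resolution_um_per_px"])
    seed = int(cfg["seed"])
    run_cfg = RunConfig.from_mapping(cfg["run"])

    paths = {
        "srs": out / "srs.tiff", "he": out / "he.tiff",
        "gt_srs": out / "gt_srs.tiff", "gt_he": out / "gt_he.tiff",
        "scene": out / "scene.json",
        "model": out / "model.npz", "history": out / "history.json",
        "srs_prob": out / "srs_prob.tiff", "srs_mask": out / "srs_mask.tiff",
        "he_mask": out / "he_mask.tiff",
        "srs_instances": out / "srs_instances.tiff",
        "he_instances": out / "he_instances.tiff",
        "counts": out / "counts.json", "metrics": out / "metrics.json",
    }
    manifest: dict = {
        "version": __version__,
        "config": cfg,
        "seeds": {"scene": seed + _SEED_SCENE, "train": seed + _SEED_TRAIN,
                  "he": seed + _SEED_HE},
        "stages": {},
        "outputs": {},
        "status": "running",
    }

    def finish_stage(name: str, t0: float, outputs: list[str]) -> None:
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3),
                                    "skipped": False}
        for key in outputs:
            manifest["outputs"][key] = str(paths[key])
        log.info("stage %s done in %.1fs", name, time.time() - t0)

    def skip_stage(name: str, outputs: list[str]) -> None:
        manifest["stages"][name] = {"skipped": True}
        for key in outputs:
            manifest["outputs"][key] = str(paths[key])
        log.info("stage %s skipped (outputs exist)", name)

    stage = "simulate"
    try:
        # --- simulate -----------------------------------------------------
        sim_outputs = ["srs", "he", "gt_srs", "gt_he", "scene"]
        if cfg["simulate"]:
            if not force and all(paths[k].exists() for k in sim_outputs):
                skip_stage("simulate", sim_outputs)
            else:
                t0 = time.time()
                scene_kwargs = dict(cfg["scene"])
                scene_kwargs.setdefault("resolution_um_per_px", res)
                scene_kwargs.setdefault("seed", seed + _SEED_SCENE)
                if "radius_um_range" in scene_kwargs:
                    scene_kwargs["radius_um_range"] = tuple(scene_kwargs["radius_um_range"])
                spec = SceneSpec(**scene_kwargs)
                srs, gt = generate_srs_scene(spec)
                he, gt_he = generate_paired_he(gt, spec)
                save_image(srs, paths["srs"])
                save_image(he, paths["he"])
                save_mask(gt, paths["gt_srs"])
                save_mask(gt_he, paths["gt_he"])
                _dump_json(spec.to_dict(), paths["scene"])
                finish_stage("simulate", t0, sim_outputs)
            srs_path, he_path = paths["srs"], paths["he"]
            train_mask_path = paths["gt_srs"]
        else:
            srs_path = Path(cfg["srs_image"]) if "srs_image" in cfg else None
            he_path = Path(cfg["he_image"]) if "he_image" in cfg else None
            train_mask_path = Path(cfg["train_mask"]) if "train_mask" in cfg else None

        srs = load_image(srs_path, "SRS", res) if srs_path else None
        he = load_image(he_path, "HE", res) if he_path else None

        # --- train ---------------------------------------------------------
        stage = "train"
        model_kwargs = dict(cfg["model"])
        if "kernels_per_level" in model_kwargs:
            model_kwargs["kernels_per_level"] = tuple(model_kwargs["kernels_per_level"])
        seg = UNetSegmenter(patch_px=run_cfg.patch_size_px,
                            random_state=seed + _SEED_TRAIN, **model_kwargs)
        if srs is not None and train_mask_path is not None:
            if not force and paths["model"].exists():
                skip_stage("train", ["model", "history"])
                seg.model_ = UNet.load(paths["model"])
            else:
                t0 = time.time()
                gt = load_instance_map(train_mask_path)
                mask = semantic_mask(gt)
                gx = tiling.split(srs.pixels, run_cfg.patch_size_px)
                gy = tiling.split(mask, run_cfg.patch_size_px)
                X = np.stack([t for _, _, t in gx.patches])
                Y = np.stack([t for _, _, t in gy.patches]).astype(np.float32)
                seg.fit(X, Y)
                seg.model_.save(paths["model"])
                _dump_json({"train_loss": seg.history_.train_loss,
                            "val_loss": seg.history_.val_loss,
                            "best_epoch": seg.history_.best_epoch,
                            "epochs_run": seg.history_.epochs_run},
                           paths["history"])
                finish_stage("train", t0, ["model", "history"])

        # --- segment-srs -----------------------------------------------------
        stage = "segment-srs"
        if srs is not None and hasattr(seg, "model_"):
            if not force and paths["srs_mask"].exists():
                skip_stage("segment-srs", ["srs_prob", "srs_mask"])
            else:
                t0 = time.time()
                prob = seg.predict_proba(srs)
                mask = (prob > run_cfg.prob_threshold).astype(np.uint8)
                tifffile.imwrite(paths["srs_prob"], prob.astype(np.float32))
                save_mask(mask, paths["srs_mask"])
                finish_stage("segment-srs", t0, ["srs_prob", "srs_mask"])

        # --- segment-he ------------------------------------------------------
        stage = "segment-he"
        if he is not None:
            if not force and paths["he_mask"].exists():
                skip_stage("segment-he", ["he_mask"])
            else:
                t0 = time.time()
                he_seg = HEKMeansSegmenter(k_clusters=run_cfg.k_clusters,
                                           patch_px=run_cfg.he_patch_size_px,
                                           random_state=seed + _SEED_HE)
                save_mask(he_seg.predict(he), paths["he_mask"])
                finish_stage("segment-he", t0, ["he_mask"])

        # --- count -----------------------------------------------------------
        stage = "count"
        results: dict[str, CountResult] = {}
        count_outputs = []
        sources = [(name, mp, key) for name, mp, key in
                   (("srs", paths["srs_mask"], "srs_instances"),
                    ("he", paths["he_mask"], "he_instances")) if mp.exists()]
        already = (not force and paths["counts"].exists()
                   and all(paths[key].exists() for _, _, key in sources))
        t0 = time.time()
        for name, mask_path, inst_key in sources:
            mask = load_image(mask_path, "MASK", res).pixels[:, :, 0]
            r = count_from_mask(mask, res, run_cfg)
            results[name] = r
            count_outputs.append(inst_key)
            if not already:
                save_mask(r.instance_map.labels, paths[inst_key])
        if results and already:
            skip_stage("count", count_outputs + ["counts"])
        elif results:
            _dump_json({k: _count_summary(v) for k, v in results.items()},
                       paths["counts"])
            finish_stage("count", t0, count_outputs + ["counts"])

        # --- evaluate ---------------------------------------------------------
        stage = "evaluate"
        if results and not force and paths["metrics"].exists():
            skip_stage("evaluate", ["metrics"])
        elif results:
            t0 = time.time()
            report: dict = {"counts": {k: v.n_cells for k, v in results.items()}}
            if cfg["simulate"] and "srs" in results:
                gt = load_instance_map(paths["gt_srs"])
                pred_mask = load_image(paths["srs_mask"], "MASK", res).pixels[:, :, 0]
                prob = tifffile.imread(paths["srs_prob"])
                pm = metrics.evaluate_masks(pred_mask, semantic_mask(gt), prob)
                report["pixel"] = dataclasses.asdict(pm)
                report["count_pe_vs_truth"] = metrics.percentage_error(
                    results["srs"].n_cells, len(np.unique(gt[gt > 0])))
            if "srs" in results and "he" in results:
                shape = results["srs"].instance_map.labels.shape
                try:
                    fovs = metrics.fov_partition(shape, run_cfg)
                except ValueError:
                    fovs = None
                if fovs and len(fovs) >= 3:
                    a = metrics.count_result_per_fov(results["srs"], fovs)
                    b = metrics.count_result_per_fov(results["he"], fovs)
                    report["agreement"] = dataclasses.asdict(metrics.agreement(a, b))
                hm = {k: metrics.density_heatmap(v.instance_map.labels, run_cfg,
                                                 v.multiplicity).tolist()
                      for k, v in results.items()}
                report["heatmaps"] = hm
            _dump_json(report, paths["metrics"])
            finish_stage("evaluate", t0, ["metrics"])

        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _dump_json(manifest, out / "manifest.json")
        raise
    _dump_json(manifest, out / "manifest.json")
    return manifest
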