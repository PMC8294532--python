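"""Desk-scale end-to-end studies on synthetic scenes.

These are the package's own reference experiments: train the reduced
U-Net on patches of the default synthetic scene and score held-out
patches; verify counting exactness and robustness to touching cells;
and measure SRS-vs-H&E count agreement per field of view.  They are
what ``scripts/acceptance.py`` recomputes.

The training profile here is the scaled single-CPU budget: kernels
(8, 16, 32), batch 8, at most 6 epochs.  On the colour-separable
synthetic scenes the loss plateaus within the first few epochs, so the
early-stopping patience of 25 epochs never binds at this cap; the full
(16..256, 300-epoch) configuration remains the package default for real
data.
"""

from __future__ import annotations

import numpy as np

from . import metrics, tiling
from .counting import count_from_mask
from .hekmeans import HEKMeansSegmenter
from .imaging import RunConfig
from .simulate import SceneSpec, generate_paired_he, generate_srs_scene, semantic_mask
from .unet import UNetSegmenter

#: scaled single-CPU training profile
STUDY_KERNELS = (8, 16, 32)
STUDY_BATCH = 8
STUDY_MAX_EPOCHS = 6
# with the epoch cap below, any patience >= the cap is equivalent to the
# default 25: early stopping can never trigger before the cap is reached
STUDY_PATIENCE = STUDY_MAX_EPOCHS


def train_study_segmenter(seed: int = 0):
    """Train the scaled U-Net on the default scene's 256 px patches.

    Returns ``(segmenter, X_test, Y_test)`` where the held-out set is a
    random 50 of the scene's patches.
    """
    spec = SceneSpec(seed=seed)
    srs, gt = generate_srs_scene(spec)
    mask = semantic_mask(gt).astype(np.float32)
    gx = tiling.split(srs.pixels, 256)
    gy = tiling.split(mask, 256)
    X = np.stack([t for _, _, t in gx.patches])
    Y = np.stack([t for _, _, t in gy.patches])
    rng = np.random.default_rng(seed + 1)
    perm = rng.permutation(len(X))
    test_idx, train_idx = perm[:50], perm[50:]
    seg = UNetSegmenter(kernels_per_level=STUDY_KERNELS, batch_size=STUDY_BATCH,
                        max_epochs=STUDY_MAX_EPOCHS, patience=STUDY_PATIENCE,
                        patch_px=256, random_state=seed)
    seg.fit(X[train_idx], Y[train_idx])
    return seg, X[test_idx], Y[test_idx]


def segmentation_study(seed: int = 0):
    """Held-out pixel-wise scores of the scaled training run.

    Returns ``(segmenter, scores)`` with accuracy/sensitivity/
    specificity/DICE over the pooled held-out pixels and the rank AUC of
    the predicted probabilities.
    """
    seg, X_test, Y_test = train_study_segmenter(seed)
    probs = seg.model_.predict_proba_patches(X_test)
    pred = (probs > seg.prob_threshold).astype(np.uint8)
    pm = metrics.evaluate_masks(pred, Y_test, probs)
    scores = {
        "dice": pm.dice, "auc": pm.auc, "accuracy": pm.accuracy,
        "sensitivity": pm.sensitivity, "specificity": pm.specificity,
        "epochs_run": seg.history_.epochs_run,
        "n_test_patches": len(X_test),
    }
    return seg, scores


def _clean_spec(seed: int, overlap: float) -> SceneSpec:
    return SceneSpec(height_px=1024, width_px=1024, n_cells=50,
                     overlap_fraction=overlap, n_artifacts=0, noise_sd=0.0,
                     he_shift_px_sd=0.0, he_dropout_prob=0.0, seed=seed)


def counting_study(seed: int = 0, n_scenes: int = 10) -> dict:
    """Counting exactness and touching-cell robustness on clean scenes.

    Counts ground-truth instance masks (isolating the morphological
    stage from segmentation quality): with isolated cells the count must
    be exact; with 30% touching pairs the per-scene percentage error is
    averaged.
    """
    cfg = RunConfig()
    exact = 0
    pes = []
    for i in range(n_scenes):
        _, gt = generate_srs_scene(_clean_spec(seed + i, 0.0))
        r = count_from_mask(semantic_mask(gt), 0.37, cfg)
        exact += int(r.n_cells == gt.max())
        _, gt2 = generate_srs_scene(_clean_spec(seed + 1000 + i, 0.3))
        r2 = count_from_mask(semantic_mask(gt2), 0.37, cfg)
        pes.append(metrics.percentage_error(r2.n_cells, gt2.max()))
    return {
        "n_scenes": n_scenes,
        "exact_fraction_isolated": exact / n_scenes,
        "mean_pe_touching": float(np.mean(pes)),
    }


def agreement_study(segmenter, seed: int = 0) -> dict:
    """SRS-vs-H&E count agreement per FOV on a fresh paired scene.

    Generates a 2048 px paired scene (cell density matching the default
    scene), segments the SRS frame with the trained model and the H&E
    frame with colour K-means, counts both, and compares per 512 px FOV.
    """
    n_cells = int(round(3000 * (2048 / 4608) ** 2))
    spec = SceneSpec(height_px=2048, width_px=2048, n_cells=n_cells,
                     n_artifacts=1, seed=seed)
    srs, gt = generate_srs_scene(spec)
    he, gt_he = generate_paired_he(gt, spec)
    cfg = RunConfig(seed=seed, fov_patches=2)  # 512 px FOVs -> 16 of them

    srs_mask = segmenter.predict(srs)
    he_mask = HEKMeansSegmenter(random_state=seed).predict(he)
    r_srs = count_from_mask(srs_mask, spec.resolution_um_per_px, cfg)
    r_he = count_from_mask(he_mask, spec.resolution_um_per_px, cfg)

    fovs = metrics.fov_partition(srs_mask.shape, cfg)
    a = metrics.count_result_per_fov(r_srs, fovs)
    b = metrics.count_result_per_fov(r_he, fovs)
    rep = metrics.agreement(a, b)
    return {
        "n_fovs": len(fovs),
        "n_true_cells": int(gt.max()),
        "srs_cells": r_srs.n_cells,
        "he_cells": r_he.n_cells,
        "srs_count_pe_vs_truth": metrics.percentage_error(r_srs.n_cells, gt.max()),
        "srs_he_count_pe": rep.pe,
        "pearson_r": rep.pearson_r,
        "mean_diff": rep.mean_diff,
        "loa_low": rep.loa_low,
        "loa_high": rep.loa_high,
        "fraction_within_loa": 1.0 - float(np.mean(rep.outside_loa)),
    }
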