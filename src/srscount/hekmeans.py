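"""Unsupervised H&E cell segmentation by colour K-means.

Pixels of each 500x500 patch are clustered in RGB space (K = 6 by
default) by Lloyd's algorithm with k-means++ seeding; the cluster whose
centroid lies closest (Euclidean) to a dark hematoxylin-blue reference
colour is labelled "cell".  This needs no annotation, which is why it
serves as the reference modality for evaluating SRS counts.

The Lloyd loop is written out explicitly so that the clustering
objective

    J(C) = sum_k sum_{x_i in c_k} ||x_i - mu_k||^2

is recorded after every assignment step; it is guaranteed non-increasing
across iterations, and tests assert this on every patch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cluster import kmeans_plusplus

from . import tiling
from .imaging import CalibratedImage, RunConfig

#: Default dark hematoxylin blue used to pick the cell cluster.
DEFAULT_CELL_RGB = (0.15, 0.15, 0.45)


@dataclass
class ClusterModel:
    """Fitted colour clustering of one pixel set."""

    K: int
    centroids: np.ndarray            # (K, d)
    assignment: np.ndarray           # (n,) cluster index per pixel
    objective_j: float               # final sum of squared distances
    j_history: list[float] = field(default_factory=list)
    n_iter: int = 0


def _sq_dists(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """(n, K) squared Euclidean distances (clipped at 0 for round-off)."""
    d2 = (X * X).sum(1)[:, None] - 2.0 * (X @ C.T) + (C * C).sum(1)[None, :]
    return np.maximum(d2, 0.0)


def kmeans_fit(pixels: np.ndarray, K: int, seed: int = 0,
               max_iter: int = 100, tol: float = 1e-6) -> ClusterModel:
    """Lloyd's algorithm from k-means++ seeding; deterministic given seed.

    Raises if ``K`` exceeds the number of distinct pixels.  The recorded
    ``j_history`` holds the objective after every assignment step and is
    non-increasing by construction.
    """
    X = np.asarray(pixels, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("pixels must be a non-empty (n, d) array")
    if K < 1:
        raise ValueError("K must be >= 1")
    n_distinct = len(np.unique(X, axis=0))
    if K > n_distinct:
        raise ValueError(f"K={K} exceeds the {n_distinct} distinct pixels")

    C, _ = kmeans_plusplus(X, n_clusters=K, random_state=seed)
    j_history: list[float] = []
    labels = np.zeros(len(X), dtype=np.int64)
    for it in range(1, max_iter + 1):
        d2 = _sq_dists(X, C)
        labels = d2.argmin(axis=1)
        j_history.append(float(d2[np.arange(len(X)), labels].sum()))
        newC = C.copy()
        for k in range(K):
            members = labels == k
            if members.any():
                newC[k] = X[members].mean(axis=0)
            else:
                # re-seed an empty cluster to the currently worst-fit pixel
                newC[k] = X[d2.min(axis=1).argmax()]
        shift = float(np.sqrt(((newC - C) ** 2).sum(axis=1)).max())
        C = newC
        if shift < tol:
            break
    d2 = _sq_dists(X, C)
    labels = d2.argmin(axis=1)
    obj = float(d2[np.arange(len(X)), labels].sum())
    j_history.append(obj)
    return ClusterModel(K=K, centroids=C, assignment=labels,
                        objective_j=obj, j_history=j_history, n_iter=it)


def select_cell_cluster(centroids: np.ndarray, reference_rgb) -> int:
    """Index of the centroid nearest the reference colour (ties -> lowest index)."""
    ref = np.asarray(reference_rgb, dtype=np.float64)
    d = np.sqrt(((centroids - ref) ** 2).sum(axis=1))
    return int(d.argmin())


def segment_he(image, run_config: RunConfig | None = None,
               color_ref=DEFAULT_CELL_RGB, max_iter: int = 50,
               tol: float = 1e-4) -> np.ndarray:
    """Binary cell mask of an RGB H&E image via per-patch colour K-means.

    The image is tiled into ``he_patch_size_px`` patches (zero-padded at
    the bottom/right edges); each patch is clustered independently and
    exactly one cluster per patch — the one nearest ``color_ref`` — is
    labelled cell.  Patch masks are reassembled losslessly.
    """
    cfg = run_config or RunConfig()
    if isinstance(image, CalibratedImage):
        if image.modality != "HE":
            raise ValueError("segment_he expects an HE image")
        arr = image.pixels
    else:
        arr = np.asarray(image, dtype=np.float32)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("H&E segmentation requires an RGB image")

    grid = tiling.split(arr, cfg.he_patch_size_px)
    masks = []
    for i, (_, _, tile) in enumerate(grid.patches):
        X = tile.reshape(-1, 3)
        # degenerate patches (uniform padding, noise-free background) can
        # have fewer distinct colours than clusters requested
        k_eff = min(cfg.k_clusters, len(np.unique(X, axis=0)))
        model = kmeans_fit(X, k_eff, seed=cfg.seed + i, max_iter=max_iter, tol=tol)
        cell = select_cell_cluster(model.centroids, color_ref)
        masks.append((model.assignment == cell).astype(np.uint8)
                     .reshape(tile.shape[:2]))
    return tiling.combine(grid, masks)


class HEKMeansSegmenter(BaseEstimator):
    """Estimator interface to :func:`segment_he` (stateless: ``fit`` is a no-op)."""

    def __init__(self, k_clusters=6, patch_px=500, reference_rgb=DEFAULT_CELL_RGB,
                 max_iter=50, tol=1e-4, random_state=0):
        self.k_clusters = k_clusters
        self.patch_px = patch_px
        self.reference_rgb = reference_rgb
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X=None, y=None):
        return self

    def predict(self, image) -> np.ndarray:
        cfg = RunConfig(seed=self.random_state, k_clusters=self.k_clusters,
                        he_patch_size_px=self.patch_px)
        return segment_he(image, cfg, color_ref=self.reference_rgb,
                          max_iter=self.max_iter, tol=self.tol)
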