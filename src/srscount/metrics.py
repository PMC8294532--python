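"""Segmentation and count-agreement evaluation.

Pixel-wise metrics (accuracy, sensitivity, specificity, DICE, AUC) for
mask-vs-annotation comparison, the percentage error of counts, and the
count-level agreement machinery used across imaging modalities:
field-of-view partitioning, centroid-rule per-FOV counting, Pearson
correlation, Bland-Altman limits of agreement, and density heat-maps.

Cross-modality comparison is count-level only — cells shift and vanish
between SRS and H&E frames of the same specimen, so pixel-wise or
instance-matched comparison across modalities is not meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.stats import rankdata

from .counting import CountResult
from .imaging import RunConfig


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class PixelMetrics:
    """Pixel-wise scores; undefined ratios are ``None``, never 0."""

    accuracy: float
    sensitivity: float | None
    specificity: float | None
    dice: float | None
    auc: float | None = None


@dataclass
class AgreementReport:
    """Count-level agreement between two modalities over matched FOVs."""

    fov_counts_a: list[int]
    fov_counts_b: list[int]
    pearson_r: float | None
    pe: float
    mean_diff: float
    loa_low: float
    loa_high: float
    outside_loa: list[bool] = field(default_factory=list)


def confusion(pred_mask: np.ndarray, true_mask: np.ndarray) -> ConfusionCounts:
    """Pixel-wise confusion counts of two equal-shape binary masks."""
    p = np.asarray(pred_mask).astype(bool)
    t = np.asarray(true_mask).astype(bool)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def auc_score(scores: np.ndarray, true_mask: np.ndarray) -> float | None:
    """Rank (Mann-Whitney) AUC: P(random cell score > random non-cell score),
    ties counting one half.  Equals the trapezoidal ROC area."""
    s = np.asarray(scores, dtype=np.float64).ravel()
    t = np.asarray(true_mask).astype(bool).ravel()
    n1 = int(t.sum())
    n0 = t.size - n1
    if n1 == 0 or n0 == 0:
        return None
    ranks = rankdata(s)
    return float((ranks[t].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def pixel_metrics(counts: ConfusionCounts, prob_map: np.ndarray | None = None,
                  true_mask: np.ndarray | None = None) -> PixelMetrics:
    """Accuracy/sensitivity/specificity/DICE from counts; AUC from scores.

    DICE = 2 TP / (2 TP + FP + FN).  Ratios with an empty denominator
    (e.g. sensitivity when there are no positive pixels) are reported as
    ``None``.
    """
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    total = counts.total
    acc = (tp + tn) / total if total else None
    sens = tp / (tp + fn) if tp + fn else None
    spec = tn / (tn + fp) if tn + fp else None
    dice = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else None
    auc = None
    if prob_map is not None:
        if true_mask is None:
            raise ValueError("AUC needs the true mask alongside the scores")
        auc = auc_score(prob_map, true_mask)
    return PixelMetrics(accuracy=acc, sensitivity=sens, specificity=spec,
                        dice=dice, auc=auc)


def evaluate_masks(pred_mask, true_mask, prob_map=None) -> PixelMetrics:
    """Convenience wrapper: confusion + metrics in one call."""
    return pixel_metrics(confusion(pred_mask, true_mask), prob_map, true_mask)


def percentage_error(n_pred: float, n_true: float) -> float:
    """PE = |N_pred - N_true| / N_true."""
    if n_true == 0:
        raise ValueError("percentage error is undefined for a true count of 0")
    return abs(n_pred - n_true) / n_true


def fov_partition(count_map_shape: tuple[int, int],
                  run_config: RunConfig | None = None
                  ) -> list[tuple[int, int, int, int]]:
    """Non-overlapping FOV rectangles (r0, c0, r1, c1), half-open.

    Each FOV is ``fov_patches x fov_patches`` patches of
    ``patch_size_px`` (2048 px square by default); trailing partial FOVs
    are dropped.  Raises if the image holds no complete FOV.
    """
    cfg = run_config or RunConfig()
    f = cfg.fov_patches * cfg.patch_size_px
    h, w = count_map_shape[:2]
    if h < f or w < f:
        raise ValueError(f"image {h}x{w} is smaller than one {f}x{f} FOV")
    return [(r * f, c * f, (r + 1) * f, (c + 1) * f)
            for r in range(h // f) for c in range(w // f)]


def _centroids(instance_map: np.ndarray) -> dict[int, tuple[float, float]]:
    labels = np.asarray(instance_map)
    ids = np.unique(labels[labels > 0])
    if len(ids) == 0:
        return {}
    cents = ndi.center_of_mass(labels > 0, labels, ids)
    return {int(i): (float(cy), float(cx)) for i, (cy, cx) in zip(ids, cents)}


def count_per_fov(instance_map: np.ndarray,
                  fovs: list[tuple[int, int, int, int]],
                  multiplicity: dict[int, int] | None = None) -> list[int]:
    """Cells per FOV by the centroid rule (each instance counted once,
    in the FOV containing its centroid), carrying oversize multiplicities."""
    multiplicity = multiplicity or {}
    counts = [0] * len(fovs)
    for lab, (cy, cx) in _centroids(instance_map).items():
        for i, (r0, c0, r1, c1) in enumerate(fovs):
            if r0 <= cy < r1 and c0 <= cx < c1:
                counts[i] += multiplicity.get(lab, 1)
                break
    return counts


def count_result_per_fov(result: CountResult, fovs) -> list[int]:
    """Per-FOV counts of a counting-stage result (multiplicities included)."""
    return count_per_fov(result.instance_map.labels, fovs, result.multiplicity)


def agreement(counts_a: list[int], counts_b: list[int]) -> AgreementReport:
    """Count agreement between two modalities over matched FOVs.

    Pearson r of the per-FOV counts (``None`` when either list has zero
    variance), percentage error of the totals (b as reference), and the
    Bland-Altman mean difference with 95% limits of agreement at
    mean +/- 1.96 sd of the per-FOV differences.
    """
    a = np.asarray(counts_a, dtype=np.float64)
    b = np.asarray(counts_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length count lists of length >= 3")
    r = None
    if a.std() > 0 and b.std() > 0:
        r = float(np.corrcoef(a, b)[0, 1])
    pe = percentage_error(a.sum(), b.sum())
    diff = a - b
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    lo, hi = mean_diff - 1.96 * sd, mean_diff + 1.96 * sd
    outside = [bool(d < lo or d > hi) for d in diff]
    return AgreementReport(fov_counts_a=[int(x) for x in counts_a],
                           fov_counts_b=[int(x) for x in counts_b],
                           pearson_r=r, pe=float(pe), mean_diff=mean_diff,
                           loa_low=float(lo), loa_high=float(hi),
                           outside_loa=outside)


def density_heatmap(instance_map: np.ndarray,
                    run_config: RunConfig | None = None,
                    multiplicity: dict[int, int] | None = None) -> np.ndarray:
    """Cell counts per ``heatmap_patch_px`` grid cell (centroid rule).

    Grid dimensions are ``ceil(H/p) x ceil(W/p)``; the grid total equals
    the whole-image centroid count.
    """
    cfg = run_config or RunConfig()
    p = cfg.heatmap_patch_px
    labels = np.asarray(instance_map)
    h, w = labels.shape
    grid = np.zeros((-(-h // p), -(-w // p)), dtype=np.int64)
    multiplicity = multiplicity or {}
    for lab, (cy, cx) in _centroids(labels).items():
        grid[int(cy) // p, int(cx) // p] += multiplicity.get(lab, 1)
    return grid
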