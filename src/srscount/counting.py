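"""From binary cell masks to cell instances and counts.

The morphological stage of the pipeline: a 3x3 opening removes
speck noise, 8-connected components become initial instances, each
component is split by marker-based watershed on its negated Euclidean
distance map (markers = connected components of the max-rescaled
distance above 0.5), and two micron-calibrated filters then drop
sub-resolution specks (equivalent diameter < 0.37 um) and vessel-like
regions (major axis > 100 um or area > 500 um^2).  Finally, instances
larger than the upper inner fence of the area distribution
(Q3 + 1.5 IQR) are counted as multiple cells by dividing by the mean
area of ordinary instances — the recovery rule for merged cells the
watershed could not separate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import regionprops
from skimage.segmentation import watershed
from sklearn.base import BaseEstimator

from .imaging import RunConfig

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class InstanceMap:
    """Integer-labelled image (0 = background) with physical resolution."""

    labels: np.ndarray
    resolution_um_per_px: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("instance labels must be integers")
        if self.resolution_um_per_px <= 0:
            raise ValueError("resolution_um_per_px must be positive")

    @property
    def n_instances(self) -> int:
        return int(self.labels.max(initial=0))


@dataclass
class RegionStats:
    """Micron-calibrated geometry of one instance."""

    label: int
    area_um2: float
    equiv_diameter_um: float
    major_axis_um: float


@dataclass
class CountResult:
    """Instances plus the final cell count and its bookkeeping.

    ``n_cells >= n_instances``: oversized instances (area above the
    upper inner fence) contribute a multiplicity > 1.  ``multiplicity``
    maps each surviving label to its contribution, so downstream
    per-FOV / heat-map counts can carry the multi-count through.
    """

    instance_map: InstanceMap
    n_instances: int
    n_cells: int
    fence_um2: float | None
    mean_cell_area_um2: float | None
    excluded_regions: list[tuple[int, str]] = field(default_factory=list)
    multiplicity: dict[int, int] = field(default_factory=dict)
    areas_um2: dict[int, float] = field(default_factory=dict)


def open_mask(mask: np.ndarray) -> np.ndarray:
    """One iteration of morphological opening with a 3x3 structuring element."""
    mask = np.asarray(mask).astype(bool)
    return ndi.binary_opening(mask, structure=_STRUCT8).astype(np.uint8)


def label_regions(mask: np.ndarray) -> np.ndarray:
    """8-connected component labelling, labels 1..n in raster order."""
    mask = np.asarray(mask).astype(bool)
    labels, _ = ndi.label(mask, structure=_STRUCT8)
    return labels.astype(np.int32)


def distance_map(region_mask: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance from each foreground pixel to the background."""
    return ndi.distance_transform_edt(np.asarray(region_mask).astype(bool))


def split_region(region_mask: np.ndarray, dist_threshold: float = 0.5) -> np.ndarray:
    """Split one connected region into instances by distance-based watershed.

    The distance map is rescaled by its maximum; connected components of
    {rescaled > dist_threshold} become markers; remaining region pixels
    are assigned by watershed on the negated (unscaled) distance map.
    The output labels partition the input region exactly.  A region with
    a single marker is returned intact.
    """
    region = np.asarray(region_mask).astype(bool)
    if not region.any():
        raise ValueError("split_region requires a non-empty region")
    dist = ndi.distance_transform_edt(region)
    rescaled = dist / dist.max()
    markers, n_markers = ndi.label(rescaled > dist_threshold, structure=_STRUCT8)
    if n_markers <= 1:
        return region.astype(np.int32)
    return watershed(-dist, markers=markers, mask=region, connectivity=2
                     ).astype(np.int32)


def segment_instances(mask: np.ndarray, dist_threshold: float = 0.5,
                      apply_opening: bool = True) -> np.ndarray:
    """Binary mask -> instance map: opening, labelling, per-region splitting."""
    mask = np.asarray(mask).astype(bool)
    if apply_opening:
        mask = open_mask(mask).astype(bool)
    initial = label_regions(mask)
    out = np.zeros_like(initial)
    next_label = 0
    for lab, sl in enumerate(ndi.find_objects(initial), start=1):
        if sl is None:
            continue
        # pad the bounding box by one pixel so the distance transform sees
        # background on all sides
        sub = np.pad(initial[sl] == lab, 1)
        parts = split_region(sub, dist_threshold)[1:-1, 1:-1]
        n_parts = parts.max()
        out[sl][parts > 0] = parts[parts > 0] + next_label
        next_label += int(n_parts)
    return out


def region_stats(instance_map: InstanceMap) -> list[RegionStats]:
    """Area, equivalent circular diameter and ellipse-fit major axis per instance."""
    res = instance_map.resolution_um_per_px
    stats = []
    for rp in regionprops(instance_map.labels):
        area = rp.area * res * res
        stats.append(RegionStats(
            label=rp.label,
            area_um2=float(area),
            equiv_diameter_um=float(2.0 * np.sqrt(area / np.pi)),
            major_axis_um=float(rp.axis_major_length * res),
        ))
    return stats


def filter_regions(instance_map: InstanceMap,
                   min_diameter_um: float = 0.37,
                   max_length_um: float = 100.0,
                   max_area_um2: float = 500.0
                   ) -> tuple[InstanceMap, list[tuple[int, str]]]:
    """Apply the micron-calibrated size filters; relabel survivors contiguously.

    Instances with equivalent circular diameter below ``min_diameter_um``
    are excluded as ``too_small``; instances whose ellipse-fit major axis
    exceeds ``max_length_um`` or whose area exceeds ``max_area_um2`` are
    excluded as ``vessel_like`` (blood vessels / microhemorrhages).
    """
    excluded: list[tuple[int, str]] = []
    keep: list[int] = []
    for st in region_stats(instance_map):
        if st.equiv_diameter_um < min_diameter_um:
            excluded.append((st.label, "too_small"))
        elif st.major_axis_um > max_length_um or st.area_um2 > max_area_um2:
            excluded.append((st.label, "vessel_like"))
        else:
            keep.append(st.label)
    relabel = np.zeros(instance_map.labels.max(initial=0) + 1, dtype=np.int32)
    for new, old in enumerate(keep, start=1):
        relabel[old] = new
    new_labels = relabel[instance_map.labels]
    return InstanceMap(new_labels, instance_map.resolution_um_per_px), excluded


def count_cells(instance_map: InstanceMap) -> CountResult:
    """Count cells with the upper-inner-fence multi-count rule.

    With >= 4 instances, the fence is Q3 + 1.5 IQR of the instance areas
    (linear-interpolation quartiles); instances above the fence count as
    ``max(2, round(area / mean area of ordinary instances))`` cells.
    With fewer instances the quartiles are unstable and every instance
    counts once.  An empty map yields ``n_cells = 0``.
    """
    labels = instance_map.labels
    res = instance_map.resolution_um_per_px
    ids, pixel_counts = np.unique(labels[labels > 0], return_counts=True)
    areas = pixel_counts.astype(float) * res * res
    n = len(ids)
    areas_by_label = {int(i): float(a) for i, a in zip(ids, areas)}
    if n == 0:
        return CountResult(instance_map, 0, 0, None, None)
    mean_area = float(areas.mean())
    multiplicity = {int(i): 1 for i in ids}
    fence = None
    if n >= 4:
        q1, q3 = np.percentile(areas, [25, 75])  # linear interpolation
        fence = float(q3 + 1.5 * (q3 - q1))
        ordinary = areas[areas <= fence]
        mean_ordinary = float(ordinary.mean()) if len(ordinary) else mean_area
        mean_area = mean_ordinary
        for i, a in zip(ids, areas):
            if a > fence:
                multiplicity[int(i)] = max(2, int(round(a / mean_ordinary)))
    n_cells = int(sum(multiplicity.values()))
    return CountResult(instance_map, n, n_cells, fence, mean_area,
                       multiplicity=multiplicity, areas_um2=areas_by_label)


def count_from_mask(mask: np.ndarray, resolution_um_per_px: float,
                    run_config: RunConfig | None = None) -> CountResult:
    """Full counting stage: mask -> opened/split/filtered instances -> count."""
    cfg = run_config or RunConfig()
    inst = segment_instances(mask, dist_threshold=cfg.dist_threshold)
    imap = InstanceMap(inst, resolution_um_per_px)
    imap, excluded = filter_regions(imap, cfg.min_diameter_um,
                                    cfg.max_length_um, cfg.max_area_um2)
    result = count_cells(imap)
    result.excluded_regions = excluded
    return result


class CellCounter(BaseEstimator):
    """Estimator interface to the counting stage.

    ``count(mask, resolution_um_per_px)`` returns a :class:`CountResult`;
    ``predict`` returns just the cell count.
    """

    def __init__(self, min_diameter_um=0.37, max_length_um=100.0,
                 max_area_um2=500.0, dist_threshold=0.5):
        self.min_diameter_um = min_diameter_um
        self.max_length_um = max_length_um
        self.max_area_um2 = max_area_um2
        self.dist_threshold = dist_threshold

    def fit(self, X=None, y=None):
        return self

    def _config(self) -> RunConfig:
        return RunConfig(min_diameter_um=self.min_diameter_um,
                         max_length_um=self.max_length_um,
                         max_area_um2=self.max_area_um2,
                         dist_threshold=self.dist_threshold)

    def count(self, mask, resolution_um_per_px: float) -> CountResult:
        return count_from_mask(mask, resolution_um_per_px, self._config())

    def predict(self, mask, resolution_um_per_px: float) -> int:
        return self.count(mask, resolution_um_per_px).n_cells
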