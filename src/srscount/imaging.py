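"""Calibrated raster I/O and run-wide configuration.

Every image that moves through the pipeline is a :class:`CalibratedImage`:
a float array in ``[0, 1]`` plus the physical pixel pitch in micrometres.
The pitch is what turns pixel counts into the micron-calibrated size
filters used during counting, so it is carried explicitly rather than
being re-read from file metadata at each stage.

Conventions: 0-based row-major coordinates, origin at the top-left, all
rectangles half-open.  SRS images keep exactly the two informative
channels in the order (green = lipid, blue = protein).
"""

from __future__ import annotations

import dataclasses
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

log = logging.getLogger("srscount")

#: Modalities understood by the pipeline.
MODALITIES = ("SRS", "HE", "MASK")

#: Red-channel tolerance above which an SRS RGB file triggers a warning.
_SRS_RED_TOL = 0.02


@dataclass
class CalibratedImage:
    """Pixel array in ``[0, 1]`` with physical resolution metadata.

    Parameters
    ----------
    pixels:
        ``H x W`` or ``H x W x C`` float array with values in ``[0, 1]``.
    resolution_um_per_px:
        Physical pixel pitch in micrometres per pixel (e.g. 0.37 or 0.18
        for the two acquisition settings the pipeline targets).
    modality:
        One of ``"SRS"`` (two channels: green lipid, blue protein),
        ``"HE"`` (RGB) or ``"MASK"`` (single channel, values in {0, 1}).
    """

    pixels: np.ndarray
    resolution_um_per_px: float
    modality: str

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float32)
        if px.ndim == 2:
            px = px[:, :, None]
        if px.ndim != 3:
            raise ValueError(f"pixels must be HxW or HxWxC, got shape {px.shape}")
        h, w, c = px.shape
        if h < 1 or w < 1 or c not in (1, 2, 3):
            raise ValueError(f"invalid image shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel values must be finite")
        if px.min() < 0 or px.max() > 1:
            raise ValueError("pixel values must lie in [0, 1]")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        if self.modality == "SRS" and c != 2:
            raise ValueError("SRS images carry exactly 2 channels (green, blue)")
        if self.modality == "HE" and c != 3:
            raise ValueError("HE images must be RGB")
        if self.modality == "MASK":
            if c != 1:
                raise ValueError("MASK images are single channel")
            vals = np.unique(px)
            if not np.all(np.isin(vals, (0.0, 1.0))):
                raise ValueError("MASK values must be in {0, 1}")
        if not self.resolution_um_per_px > 0:
            raise ValueError("resolution_um_per_px must be positive")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class RunConfig:
    """Run-wide constants of the counting pipeline.

    Defaults are the working values of the pipeline: 256 px U-Net
    patches, 500 px H&E clustering patches with six clusters, 8x8-patch
    fields of view, 512 px heat-map cells, and the micron-calibrated
    region filters (minimum equivalent diameter 0.37 um; vessel-like
    exclusion above 100 um length or 500 um^2 area).
    """

    seed: int = 0
    patch_size_px: int = 256
    he_patch_size_px: int = 500
    fov_patches: int = 8
    heatmap_patch_px: int = 512
    min_diameter_um: float = 0.37
    max_length_um: float = 100.0
    max_area_um2: float = 500.0
    k_clusters: int = 6
    prob_threshold: float = 0.5
    dist_threshold: float = 0.5

    def __post_init__(self) -> None:
        for name in ("patch_size_px", "he_patch_size_px", "fov_patches", "heatmap_patch_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("min_diameter_um", "max_length_um", "max_area_um2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("prob_threshold", "dist_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.k_clusters < 1:
            raise ValueError("k_clusters must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a config from a YAML or TOML file mirroring the field names."""
        path = Path(path)
        if path.suffix == ".toml":
            with open(path, "rb") as fh:
                data = tomllib.load(fh)
        else:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        return cls(**data)


def _read_raster(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    import imageio.v3 as iio

    return iio.imread(path)


def _to_unit_range(arr: np.ndarray) -> np.ndarray:
    """Scale integer rasters by their dtype maximum; pass floats through."""
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float32) / np.iinfo(arr.dtype).max
    if arr.dtype == bool:
        return arr.astype(np.float32)
    arr = arr.astype(np.float32)
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise ValueError("float raster values must already lie in [0, 1]")
    return arr


def load_image(path: str | Path, modality: str, resolution_um_per_px: float) -> CalibratedImage:
    """Load a raster as a calibrated image.

    SRS RGB files drop the (nominally empty) red channel and keep
    (green, blue) in that order; a non-zero red channel is logged as a
    warning and discarded anyway.  Masks are binarised (non-zero -> 1).
    Integer intensities are rescaled to ``[0, 1]`` by the dtype maximum.
    """
    path = Path(path)
    if modality not in MODALITIES:
        raise ValueError(f"modality must be one of {MODALITIES}")
    arr = _read_raster(path)

    if modality == "MASK":
        if arr.ndim == 3:
            if arr.shape[2] == 1:
                arr = arr[:, :, 0]
            else:
                raise ValueError("mask rasters must be single channel")
        px = (np.asarray(arr) > 0).astype(np.float32)
        return CalibratedImage(px, resolution_um_per_px, "MASK")

    arr = _to_unit_range(arr)
    if modality == "SRS":
        if arr.ndim == 2:
            raise ValueError("SRS rasters need (green, blue) channels")
        if arr.shape[2] == 3:
            red = arr[:, :, 0]
            if float(red.max(initial=0.0)) > _SRS_RED_TOL:
                log.warning(
                    "SRS file %s has non-zero red channel (max %.3f); discarding it",
                    path, float(red.max()),
                )
            arr = arr[:, :, 1:3]
        elif arr.shape[2] != 2:
            raise ValueError(f"SRS rasters must have 2 or 3 channels, got {arr.shape[2]}")
        return CalibratedImage(arr, resolution_um_per_px, "SRS")

    # HE
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("HE rasters must be RGB")
    return CalibratedImage(arr, resolution_um_per_px, "HE")


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask or instance map as 16-bit single-channel TIFF.

    Round-trip contract: ``load_instance_map(save_mask(m)) == m`` for
    non-negative integer maps, and ``load_image(..., "MASK")`` recovers a
    binary mask exactly.
    """
    arr = np.asarray(mask)
    if arr.dtype == bool:
        arr = arr.astype(np.uint16)
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.mod(arr, 1) == 0):
            raise ValueError("mask labels must be integers")
        arr = arr.astype(np.int64)
    if arr.min(initial=0) < 0:
        raise ValueError("mask labels must be non-negative")
    if arr.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("instance labels exceed 16-bit range")
    tifffile.imwrite(Path(path), arr.astype(np.uint16))


def load_instance_map(path: str | Path) -> np.ndarray:
    """Read an integer instance map written by :func:`save_mask` (no rescaling)."""
    arr = tifffile.imread(Path(path))
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("instance maps must be integer rasters")
    return arr.astype(np.int32)


def save_image(image: CalibratedImage, path: str | Path) -> None:
    """Write a calibrated image as an 8-bit raster (SRS gets an empty red channel)."""
    px = image.pixels
    if image.modality == "SRS":
        rgb = np.zeros((*px.shape[:2], 3), dtype=np.float32)
        rgb[:, :, 1:3] = px
        px = rgb
    arr = np.round(px * 255).astype(np.uint8)
    if arr.shape[2] == 1:
        arr = arr[:, :, 0]
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, arr)
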