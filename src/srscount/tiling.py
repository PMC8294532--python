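"""Split-and-combine tiling.

Large acquisitions are processed as fixed-size patches and the per-patch
results are reassembled exactly.  The grid is non-overlapping and padded
with zeros on the bottom/right edges, so ``combine(split(M)) == M`` for
any array: every original pixel lives in exactly one patch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PatchGrid:
    """Bookkeeping for a lossless split of one image into square tiles.

    ``patches`` holds ``(row_index, col_index, pixel_array)`` in row-major
    order; ``fully_padded`` flags tiles that contain no original pixels
    (emitted anyway to keep reassembly trivial).
    """

    orig_h: int
    orig_w: int
    patch_px: int
    pad_bottom: int
    pad_right: int
    patches: list[tuple[int, int, np.ndarray]] = field(default_factory=list)
    fully_padded: list[bool] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return (self.orig_h + self.pad_bottom) // self.patch_px

    @property
    def n_cols(self) -> int:
        return (self.orig_w + self.pad_right) // self.patch_px


def split(image: np.ndarray, patch_px: int) -> PatchGrid:
    """Partition ``image`` (HxW or HxWxC) into a zero-padded grid of tiles."""
    if patch_px <= 0:
        raise ValueError("patch_px must be positive")
    image = np.asarray(image)
    if image.ndim not in (2, 3) or image.shape[0] < 1 or image.shape[1] < 1:
        raise ValueError(f"image must be non-empty HxW or HxWxC, got {image.shape}")
    h, w = image.shape[:2]
    pad_b = (-h) % patch_px
    pad_r = (-w) % patch_px
    pad_spec = ((0, pad_b), (0, pad_r)) + (((0, 0),) if image.ndim == 3 else ())
    padded = np.pad(image, pad_spec, mode="constant")
    grid = PatchGrid(h, w, patch_px, pad_b, pad_r)
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            tile = padded[r * patch_px:(r + 1) * patch_px, c * patch_px:(c + 1) * patch_px]
            grid.patches.append((r, c, tile))
            grid.fully_padded.append(r * patch_px >= h or c * patch_px >= w)
    return grid


def combine(grid: PatchGrid, per_patch_arrays: list[np.ndarray] | None = None) -> np.ndarray:
    """Reassemble per-patch results and crop the padding.

    ``per_patch_arrays`` defaults to the grid's own tiles (identity round
    trip).  Each array must be ``patch_px x patch_px`` (optionally with
    trailing channel axes).
    """
    p = grid.patch_px
    if per_patch_arrays is None:
        per_patch_arrays = [tile for _, _, tile in grid.patches]
    if len(per_patch_arrays) != len(grid.patches):
        raise ValueError(
            f"expected {len(grid.patches)} per-patch arrays, got {len(per_patch_arrays)}"
        )
    arrays = [np.asarray(a) for a in per_patch_arrays]
    for a in arrays:
        if a.shape[:2] != (p, p):
            raise ValueError(f"per-patch arrays must be {p}x{p}, got {a.shape}")
    extra = arrays[0].shape[2:]
    if any(a.shape[2:] != extra for a in arrays):
        raise ValueError("per-patch arrays disagree on channel shape")
    full = np.zeros((grid.n_rows * p, grid.n_cols * p) + extra, dtype=arrays[0].dtype)
    for (r, c, _), a in zip(grid.patches, arrays):
        full[r * p:(r + 1) * p, c * p:(c + 1) * p] = a
    return full[: grid.orig_h, : grid.orig_w]
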