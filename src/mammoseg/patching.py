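"""Patch extraction and patch-prediction aggregation.

Training patches are cut centered on each mass component; test-time patches
tile the frame with 50% overlap (stride = patch_size / 2), the final offset
clamped so the last patch ends flush with the border.  Per-patch probability
maps are fused with a per-pixel max (saliency) and binary masks with a
logical OR, so a mass detected in any single patch survives aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["PatchGrid", "SaliencyMap", "extract_mass_centered_patches",
           "extract_overlapping_patches", "aggregate_saliency",
           "aggregate_binary"]


@dataclass
class SaliencyMap:
    """Per-pixel mass probability grid in [0,1] plus its coordinate frame
    ("model-space", "padded-N-space" or "original-space")."""

    grid: np.ndarray
    frame: str = "padded-N-space"

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=np.float64)
        if g.min() < -1e-9 or g.max() > 1 + 1e-9:
            raise ValueError("saliency values must lie in [0, 1]")
        self.grid = np.clip(g, 0.0, 1.0)


@dataclass
class PatchGrid:
    """Fixed-size patches plus their top-left offsets in the source frame."""

    patches: list[np.ndarray]
    offsets: list[tuple[int, int]]
    source_shape: tuple[int, int]
    patch_size: int
    stride: int

    def __len__(self) -> int:
        return len(self.patches)

    def replace_patches(self, new_patches: list[np.ndarray]) -> "PatchGrid":
        """Same geometry, different patch contents (e.g. model predictions)."""
        if len(new_patches) != len(self.patches):
            raise ValueError("patch count mismatch")
        return PatchGrid(patches=list(new_patches), offsets=list(self.offsets),
                         source_shape=self.source_shape,
                         patch_size=self.patch_size, stride=self.stride)


def extract_mass_centered_patches(image: np.ndarray, mask: np.ndarray,
                                  patch_size: int):
    """One ``(image patch, mask patch)`` pair per connected mass component,
    each window centered on the component centroid and zero-padded where it
    overruns the frame so the mass stays centered."""
    img = np.asarray(image, dtype=np.float64)
    msk = np.asarray(mask)
    labels, n = ndimage.label(msk > 0)
    if n == 0:
        raise ValueError("mask has no mass component")
    half = patch_size // 2
    pad_img = [(patch_size, patch_size), (patch_size, patch_size)] + \
        [(0, 0)] * (img.ndim - 2)
    img_p = np.pad(img, pad_img, mode="constant")
    msk_p = np.pad(msk, patch_size, mode="constant")
    out = []
    for comp in range(1, n + 1):
        cy, cx = ndimage.center_of_mass(labels == comp)
        r0 = int(round(cy)) - half + patch_size
        c0 = int(round(cx)) - half + patch_size
        out.append((img_p[r0:r0 + patch_size, c0:c0 + patch_size].copy(),
                    msk_p[r0:r0 + patch_size, c0:c0 + patch_size].copy()))
    return out


def _axis_offsets(side: int, patch_size: int, stride: int) -> list[int]:
    """Offsets 0, stride, 2*stride, ... with the final one clamped to
    ``side - patch_size`` so the last patch ends at the border."""
    last = side - patch_size
    offs = [o for o in range(0, side, stride) if o <= last]
    if not offs or offs[-1] != last:
        offs.append(last)
    return offs


def extract_overlapping_patches(image: np.ndarray, patch_size: int,
                                stride: int | None = None) -> PatchGrid:
    """Tile the frame with overlapping ``patch_size`` windows.

    Default stride is ``patch_size // 2`` (50% overlap).  An image smaller
    than ``patch_size`` on either axis is zero-padded on the bottom/right up
    to ``patch_size``; ``source_shape`` records the padded frame.
    """
    if stride is None:
        stride = patch_size // 2
    if stride < 1:
        raise ValueError("stride must be >= 1")
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape[:2]
    if h < patch_size or w < patch_size:
        pad = [(0, max(patch_size - h, 0)), (0, max(patch_size - w, 0))] + \
            [(0, 0)] * (img.ndim - 2)
        img = np.pad(img, pad, mode="constant")
        h, w = img.shape[:2]
    patches, offsets = [], []
    for r0 in _axis_offsets(h, patch_size, stride):
        for c0 in _axis_offsets(w, patch_size, stride):
            patches.append(img[r0:r0 + patch_size, c0:c0 + patch_size].copy())
            offsets.append((r0, c0))
    return PatchGrid(patches=patches, offsets=offsets, source_shape=(h, w),
                     patch_size=patch_size, stride=stride)


def _check_grid(grid: PatchGrid) -> None:
    h, w = grid.source_shape
    ps = grid.patch_size
    for (r0, c0) in grid.offsets:
        if not (0 <= r0 <= h - ps and 0 <= c0 <= w - ps):
            raise ValueError(f"offset ({r0}, {c0}) outside frame {grid.source_shape}")


def aggregate_saliency(patch_maps: PatchGrid) -> np.ndarray:
    """Per-pixel maximum of the covering patch probability maps."""
    _check_grid(patch_maps)
    out = np.zeros(patch_maps.source_shape, dtype=np.float64)
    ps = patch_maps.patch_size
    for patch, (r0, c0) in zip(patch_maps.patches, patch_maps.offsets):
        view = out[r0:r0 + ps, c0:c0 + ps]
        np.maximum(view, patch, out=view)
    return out


def aggregate_binary(patch_masks: PatchGrid) -> np.ndarray:
    """Logical OR of the covering patch masks."""
    _check_grid(patch_masks)
    out = np.zeros(patch_masks.source_shape, dtype=bool)
    ps = patch_masks.patch_size
    for patch, (r0, c0) in zip(patch_masks.patches, patch_masks.offsets):
        out[r0:r0 + ps, c0:c0 + ps] |= np.asarray(patch) > 0
    return out.astype(np.uint8)
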