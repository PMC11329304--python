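"""Mammogram preprocessing with an invertible geometry record.

Pipeline (in order): orient the breast against the left edge, crop the
largest foreground contour, pad to a square of side N, truncation-normalize
intensities using the 5th/99th percentiles of the breast region, synthesize
a three-channel image (normalized + CLAHE at clip limits 0.01 and 0.02),
and resize to the model input size.  Every geometric step is captured in a
:class:`CropRecord` so that model-space maps can be restored pixel-for-pixel
to the original image frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import exposure, filters, transform

__all__ = [
    "CropRecord", "orient_flip", "crop_breast_region", "pad_to_square",
    "truncate_normalize", "enhance_clahe", "compose_three_channel",
    "preprocess", "preprocess_to_nspace", "restore_to_original", "augment_pair",
    "read_image", "resize_image", "resize_mask", "binarize",
]


@dataclass
class CropRecord:
    """Invertible geometry linking model space back to the original frame.

    ``crop_box`` is half-open ``(row0, col0, row1, col1)`` in flipped-image
    coordinates; ``N = max(crop height, crop width)`` is the padded square
    side; ``pad`` is the (rows, cols) of zeros appended on the bottom/right.
    """

    flipped: bool
    crop_box: tuple[int, int, int, int]
    pad: tuple[int, int]
    original_size: tuple[int, int]
    model_size: int
    N: int

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "CropRecord":
        d = json.loads(s)
        return cls(flipped=d["flipped"],
                   crop_box=tuple(d["crop_box"]),
                   pad=tuple(d["pad"]),
                   original_size=tuple(d["original_size"]),
                   model_size=d["model_size"],
                   N=d["N"])


def binarize(mask: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    return (np.asarray(mask) > threshold).astype(np.uint8)


def _foreground(image: np.ndarray) -> np.ndarray:
    """Foreground = pixels above Otsu's threshold (all-constant image: none)."""
    img = np.asarray(image, dtype=np.float64)
    if img.max() == img.min():
        return np.zeros(img.shape, dtype=bool)
    t = filters.threshold_otsu(img)
    return img > t


def orient_flip(image: np.ndarray, mask: np.ndarray | None = None):
    """Mirror horizontally so the breast sits against the LEFT edge.

    The test is whether the foreground column-centroid falls in the right
    half of the frame; an all-background image passes through unflipped.
    Returns ``(image, mask, flipped)``.
    """
    img = np.asarray(image)
    fg = _foreground(img)
    flipped = False
    if fg.any():
        col_centroid = np.mean(np.nonzero(fg)[1])
        if col_centroid > (img.shape[1] - 1) / 2.0:
            img = img[:, ::-1].copy()
            if mask is not None:
                mask = np.asarray(mask)[:, ::-1].copy()
            flipped = True
    return img, mask, flipped


def crop_breast_region(image: np.ndarray):
    """Tight bounding box of the largest connected foreground component.

    Returns ``(cropped image, crop_box)`` with a half-open 0-based box.
    Raises ``ValueError`` when no foreground pixel exists.
    """
    img = np.asarray(image)
    fg = _foreground(img)
    if not fg.any():
        raise ValueError("empty image: no foreground pixel above threshold")
    labels, n = ndimage.label(fg)
    if n > 1:
        areas = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        keep = int(np.argmax(areas)) + 1
        fg = labels == keep
    rows = np.nonzero(fg.any(axis=1))[0]
    cols = np.nonzero(fg.any(axis=0))[0]
    box = (int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1)
    return img[box[0]:box[2], box[1]:box[3]], box


def pad_to_square(image: np.ndarray, mask: np.ndarray | None = None):
    """Zero-pad on the right and bottom up to side ``N = max(H, W)``.

    Returns ``(padded image, padded mask, (rows_added, cols_added))``.
    """
    img = np.asarray(image)
    h, w = img.shape[:2]
    n = max(h, w)
    pad_r, pad_c = n - h, n - w
    pad_width = [(0, pad_r), (0, pad_c)] + [(0, 0)] * (img.ndim - 2)
    out = np.pad(img, pad_width, mode="constant")
    out_mask = None
    if mask is not None:
        out_mask = np.pad(np.asarray(mask), [(0, pad_r), (0, pad_c)], mode="constant")
    return out, out_mask, (pad_r, pad_c)


def truncate_normalize(image: np.ndarray, region_mask: np.ndarray) -> np.ndarray:
    """Clip to the breast region's [p5, p99] and min-max normalize with them.

    Percentiles are computed with linear interpolation over the sorted
    intensities of ``region_mask`` pixels only; the resulting (p5, p99)
    window is then applied to the whole frame, so background stays 0 after
    normalization.  A constant region degenerates to an all-zero output.
    """
    img = np.asarray(image, dtype=np.float64)
    region = np.asarray(region_mask, dtype=bool)
    if not region.any():
        raise ValueError("empty region mask")
    vals = img[region]
    p5, p99 = np.percentile(vals, [5.0, 99.0])
    if p99 <= p5:
        return np.zeros_like(img)
    return (np.clip(img, p5, p99) - p5) / (p99 - p5)


def enhance_clahe(image: np.ndarray, clip_limit: float,
                  tile_grid: int = 8) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on a [0,1] image.

    ``clip_limit`` is on the normalized histogram scale; the tile grid
    defaults to 8x8.  A constant image is returned unchanged.
    """
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    img = np.asarray(image, dtype=np.float64)
    if img.max() == img.min():
        return img.copy()
    ksize = (max(img.shape[0] // tile_grid, 1), max(img.shape[1] // tile_grid, 1))
    out = exposure.equalize_adapthist(np.clip(img, 0, 1), kernel_size=ksize,
                                      clip_limit=clip_limit)
    return np.clip(out, 0.0, 1.0)


def compose_three_channel(norm: np.ndarray) -> np.ndarray:
    """Stack [normalized, CLAHE(0.01), CLAHE(0.02)] into an H x W x 3 image."""
    norm = np.asarray(norm, dtype=np.float64)
    return np.stack([norm,
                     enhance_clahe(norm, 0.01),
                     enhance_clahe(norm, 0.02)], axis=-1)


def resize_image(image: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Bilinear resize preserving range (no anti-aliasing: maps stay sharp)."""
    return transform.resize(np.asarray(image, dtype=np.float64), shape,
                            order=1, mode="edge", anti_aliasing=False,
                            preserve_range=True)


def resize_mask(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resize followed by re-binarization."""
    out = transform.resize(np.asarray(mask, dtype=np.float64), shape, order=0,
                           mode="edge", anti_aliasing=False, preserve_range=True)
    return binarize(out)


def preprocess_to_nspace(image: np.ndarray, mask: np.ndarray | None = None,
                         model_size: int = 512):
    """Pipeline up to (but excluding) the final resize: flip, crop, pad to
    the N x N square, truncate-normalize on the breast region, synthesize
    the three-channel image.  Returns ``(three_channel N x N x 3, mask_N,
    CropRecord)`` — the padded-square frame patch extraction operates in.
    """
    img = np.asarray(image, dtype=np.float64)
    original_size = img.shape
    img, mask, flipped = orient_flip(img, mask)
    cropped, box = crop_breast_region(img)
    mask_c = None if mask is None else np.asarray(mask)[box[0]:box[2], box[1]:box[3]]
    padded, mask_p, pad = pad_to_square(cropped, mask_c)
    region = _foreground(padded)
    norm = truncate_normalize(padded, region if region.any() else padded > -1)
    three = compose_three_channel(norm)
    record = CropRecord(flipped=flipped, crop_box=box, pad=pad,
                        original_size=tuple(original_size),
                        model_size=model_size, N=padded.shape[0])
    return three, mask_p, record


def preprocess(image: np.ndarray, mask: np.ndarray | None = None,
               model_size: int = 512):
    """Full pipeline: flip, crop, pad, truncate-normalize, three-channel,
    resize.  Returns ``(three_channel model_size^2 x 3, mask or None,
    CropRecord)``; the mask follows the same geometry with nearest-neighbour
    resizing."""
    three, mask_p, record = preprocess_to_nspace(image, mask, model_size)
    three_r = np.clip(resize_image(three, (model_size, model_size)), 0.0, 1.0)
    mask_r = None if mask_p is None else resize_mask(mask_p, (model_size, model_size))
    return three_r, mask_r, record


def restore_to_original(model_space_map: np.ndarray, record: CropRecord) -> np.ndarray:
    """Invert the preprocessing geometry on a model-space 2-D map.

    Bilinear-resizes back to N x N, strips the padding, places the crop into
    a zero canvas at ``crop_box`` and un-flips.  Output shape equals
    ``record.original_size``; pixels outside the crop box are 0.
    """
    m = np.asarray(model_space_map, dtype=np.float64)
    if m.shape != (record.model_size, record.model_size):
        raise ValueError(f"map shape {m.shape} != model size {record.model_size}")
    n = record.N
    full = resize_image(m, (n, n)) if m.shape != (n, n) else m
    r0, c0, r1, c1 = record.crop_box
    crop = full[: r1 - r0, : c1 - c0]
    canvas = np.zeros(record.original_size, dtype=np.float64)
    canvas[r0:r1, c0:c1] = crop
    if record.flipped:
        canvas = canvas[:, ::-1].copy()
    return canvas


def augment_pair(image: np.ndarray, mask: np.ndarray,
                 params: dict | None = None, seed: int | None = None):
    """Random (or explicit) rotation / translation / horizontal flip applied
    identically to image (bilinear) and mask (nearest + re-binarize).

    ``params`` keys: ``rotation_deg`` (|deg| <= 30), ``translate_frac``
    ((dr, dc) each in [-0.2, 0.2], as a fraction of the side), ``hflip``.
    When ``params`` is None the transform is drawn from those ranges using
    ``seed``.  Out-of-frame regions are filled with 0.
    """
    img = np.asarray(image, dtype=np.float64)
    msk = np.asarray(mask)
    h, w = img.shape[:2]
    if params is None:
        rng = np.random.default_rng(seed)
        params = {"rotation_deg": float(rng.uniform(-30, 30)),
                  "translate_frac": (float(rng.uniform(-0.2, 0.2)),
                                     float(rng.uniform(-0.2, 0.2))),
                  "hflip": bool(rng.random() < 0.5)}
    rot = float(params.get("rotation_deg", 0.0))
    tr, tc = params.get("translate_frac", (0.0, 0.0))
    hflip = bool(params.get("hflip", False))
    if abs(rot) > 30 + 1e-9:
        raise ValueError("rotation_deg must satisfy |deg| <= 30")
    if not (-0.2 - 1e-9 <= tr <= 0.2 + 1e-9 and -0.2 - 1e-9 <= tc <= 0.2 + 1e-9):
        raise ValueError("translate_frac components must lie in [-0.2, 0.2]")

    if hflip:
        img = img[:, ::-1].copy()
        msk = msk[:, ::-1].copy()

    # rotate about the image center, then translate; skimage warps use
    # (x, y) = (col, row) conventions
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    tform = (transform.SimilarityTransform(translation=-center)
             + transform.SimilarityTransform(rotation=np.deg2rad(rot))
             + transform.SimilarityTransform(translation=center)
             + transform.SimilarityTransform(translation=(tc * w, tr * h)))
    img_out = transform.warp(img, tform.inverse, order=1, cval=0.0,
                             preserve_range=True)
    msk_out = transform.warp(msk.astype(np.float64), tform.inverse, order=0,
                             cval=0.0, preserve_range=True)
    return img_out, binarize(msk_out)


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale PNG/TIFF/DICOM into a float array scaled to [0,1].

    DICOM pixel data gets rescale slope/intercept applied before min-max
    scaling; integer rasters are divided by their dtype maximum.
    """
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + intercept
        lo, hi = arr.min(), arr.max()
        return (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    import imageio.v3 as iio

    raw = iio.imread(path)
    arr = raw[..., :3].mean(axis=-1) if raw.ndim == 3 else raw
    arr = arr.astype(np.float64)
    if np.issubdtype(raw.dtype, np.integer):
        return arr / np.iinfo(raw.dtype).max
    hi = arr.max()
    return arr / hi if hi > 1 else arr
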