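"""End-to-end cascade inference.

Stage 1 (presegmenter) turns a preprocessed mammogram into a saliency map:
in *patch* mode, overlapping patches (50% stride) are pushed through the
patch U-net and the per-patch probability maps are max-fused; in *whole*
mode a single forward pass over the resized image is the map.  Stage 2
resizes image and saliency to the cascade model size, runs the PSA-guided
Attention U-net, thresholds, and restores the result to the original image
frame through the :class:`~mammoseg.preprocess.CropRecord`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .metrics import MetricsReport, compute_metrics
from .networks import CascadeAttentionUNet, UNet
from .patching import SaliencyMap, extract_overlapping_patches, \
    aggregate_saliency
from .preprocess import binarize, preprocess_to_nspace, \
    resize_image, restore_to_original

__all__ = ["CascadeBundle", "presegmenter_saliency", "run_cascade",
           "save_saliency", "load_saliency"]


@dataclass
class CascadeBundle:
    """Everything needed to run the two-stage pipeline on a raw image."""

    presegmenter_mode: str  # "patch" | "whole"
    presegmenter: UNet
    cascade: CascadeAttentionUNet
    patch_size: int = 1024
    stride: int = 512
    preseg_input_size: int = 256
    cascade_input_size: int = 512
    threshold: float = 0.5

    def validate(self, require_cascade: bool = True) -> None:
        if self.presegmenter_mode not in ("patch", "whole"):
            raise ValueError(f"unknown presegmenter mode {self.presegmenter_mode!r}")
        if self.presegmenter is None:
            raise ValueError("bundle is missing the presegmenter model")
        if require_cascade and self.cascade is None:
            raise ValueError("bundle is missing the cascade model")
        if self.presegmenter_mode == "patch" and self.stride < 1:
            raise ValueError("patch mode requires a positive stride")


def _predict_patch(model: UNet, patch3c: np.ndarray, model_input: int) -> np.ndarray:
    """Resize a patch to the model input, predict, resize the probability
    map back to patch size (bilinear both ways)."""
    ps = patch3c.shape[0]
    small = np.clip(resize_image(patch3c, (model_input, model_input)), 0, 1)
    prob = model.predict(small)
    return np.clip(resize_image(prob, (ps, ps)), 0.0, 1.0)


def presegmenter_saliency(image3c: np.ndarray, bundle: CascadeBundle) -> SaliencyMap:
    """First-stage saliency map for a preprocessed three-channel image.

    Patch mode expects the padded-N-space image and returns an N-space map
    (overlapping patch predictions max-fused, no thresholding); whole mode
    expects/returns the presegmenter's model-space frame.
    """
    bundle.validate(require_cascade=False)
    img = np.asarray(image3c, dtype=np.float64)
    if bundle.presegmenter_mode == "whole":
        small = np.clip(resize_image(
            img, (bundle.preseg_input_size, bundle.preseg_input_size)), 0, 1)
        return SaliencyMap(grid=bundle.presegmenter.predict(small),
                           frame="model-space")

    n = img.shape[0]
    grid = extract_overlapping_patches(img, bundle.patch_size, bundle.stride)
    preds = [_predict_patch(bundle.presegmenter, p, bundle.preseg_input_size)
             for p in grid.patches]
    fused = aggregate_saliency(grid.replace_patches(preds))
    return SaliencyMap(grid=fused[:n, :n], frame="padded-N-space")


def run_cascade(image: np.ndarray, bundle: CascadeBundle,
                gt_mask: np.ndarray | None = None):
    """Full two-stage inference on a raw grayscale image.

    Returns ``(binary mask in original space, SaliencyMap in original
    space, MetricsReport or None)``.
    """
    bundle.validate()
    cs = bundle.cascade_input_size
    three_n, _, record = preprocess_to_nspace(image, None, model_size=cs)

    sal = presegmenter_saliency(three_n, bundle)
    sal_n = sal.grid if sal.frame == "padded-N-space" else \
        np.clip(resize_image(sal.grid, (record.N, record.N)), 0, 1)

    img_model = np.clip(resize_image(three_n, (cs, cs)), 0, 1)
    sal_model = np.clip(resize_image(sal_n, (cs, cs)), 0, 1)
    prob = bundle.cascade.predict(img_model, sal_model)
    pred_model = binarize(prob, bundle.threshold)

    pred_orig = binarize(restore_to_original(pred_model.astype(np.float64), record))
    sal_orig = np.clip(restore_to_original(sal_model, record), 0, 1)

    report: MetricsReport | None = None
    if gt_mask is not None:
        report = compute_metrics(pred_orig, gt_mask)
    return pred_orig, SaliencyMap(grid=sal_orig, frame="original-space"), report


def save_saliency(sal: SaliencyMap, path: str | Path) -> None:
    """Persist as 16-bit PNG (value = round(p * 65535)) + JSON sidecar."""
    import imageio.v3 as iio

    path = Path(path)
    iio.imwrite(path, np.round(sal.grid * 65535).astype(np.uint16))
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"frame": sal.frame,
                                   "shape": list(sal.grid.shape)}))


def load_saliency(path: str | Path) -> SaliencyMap:
    import imageio.v3 as iio

    path = Path(path)
    grid = iio.imread(path).astype(np.float64) / 65535.0
    meta = json.loads(path.with_suffix(".json").read_text())
    return SaliencyMap(grid=grid, frame=meta["frame"])
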