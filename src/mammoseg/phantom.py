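"""Synthetic breast phantoms with exact ground-truth mass masks.

Real mammogram datasets are large, access-restricted and slow to train on.
This module generates small grayscale images that preserve the structural
features the segmentation cascade depends on — a bright breast region
against a dark background, and one or more brighter, irregularly shaped
masses fully contained in the tissue — together with pixel-exact masks, so
every downstream stage (preprocessing geometry, patch extraction, training,
aggregation, evaluation) can be exercised deterministically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = ["PhantomConfig", "PhantomSample", "generate_phantom", "generate_dataset"]


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of one synthetic mammogram-like image.

    ``boundary_irregularity`` in [0, 1] controls the angular jitter of each
    mass outline (0 = smooth ellipse); masses with irregularity above 0.5
    are tagged "malignant", purely as a pass-through label for stratified
    reporting.  ``n_masses_range``, when set, overrides ``n_masses`` with a
    per-sample draw (inclusive bounds) in :func:`generate_dataset`.
    """

    image_size: int = 256
    n_masses: int = 1
    mass_radius_range: tuple[float, float] = (10.0, 24.0)
    mass_contrast_range: tuple[float, float] = (0.25, 0.45)
    texture_noise_sd: float = 0.04
    breast_shape: str = "half-disc-left"
    boundary_irregularity: float = 0.3
    seed: int = 0
    n_masses_range: tuple[int, int] | None = None
    place_near_edge: bool = False

    def validate(self) -> None:
        if self.image_size < 32:
            raise ValueError(f"image_size must be >= 32, got {self.image_size}")
        if self.n_masses < 0:
            raise ValueError("n_masses must be non-negative")
        lo, hi = self.mass_radius_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid mass_radius_range {self.mass_radius_range}")
        if hi >= self.image_size / 2:
            raise ValueError("mass_radius_range.max must be < image_size / 2")
        clo, chi = self.mass_contrast_range
        if not (0 <= clo <= chi <= 1):
            raise ValueError(f"invalid mass_contrast_range {self.mass_contrast_range}")
        if self.texture_noise_sd < 0:
            raise ValueError("texture_noise_sd must be non-negative")
        if self.breast_shape not in ("half-disc-left", "half-disc-right"):
            raise ValueError(f"unknown breast_shape {self.breast_shape!r}")
        if not (0 <= self.boundary_irregularity <= 1):
            raise ValueError("boundary_irregularity must lie in [0, 1]")


@dataclass
class PhantomSample:
    """A generated image/mask pair plus per-mass bookkeeping.

    ``mass_records`` holds one ``(row, col, equivalent_radius, label)`` tuple
    per embedded mass; the number of connected mask components always equals
    ``len(mass_records)``.
    """

    image: np.ndarray
    mask: np.ndarray
    mass_records: list[tuple[float, float, float, str]] = field(default_factory=list)
    seed: int = 0


def _breast_mask(size: int, shape: str, rng: np.random.Generator) -> np.ndarray:
    """Boolean half-disc (elliptical) anchored on the left or right edge."""
    rr, cc = np.mgrid[0:size, 0:size]
    cy = size / 2.0
    # ellipse-ish half disc: semi-axes a (rows), b (cols)
    a = 0.47 * size * (1.0 + 0.05 * rng.uniform(-1, 1))
    b = 0.75 * size * (1.0 + 0.05 * rng.uniform(-1, 1))
    if shape == "half-disc-left":
        x = cc
    else:
        x = (size - 1) - cc
    return ((rr - cy) / a) ** 2 + (x / b) ** 2 <= 1.0


def _irregular_blob(size: int, center: tuple[float, float], radius: float,
                    irregularity: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean mask of an ellipse whose radius is jittered by low-order
    angular harmonics scaled by ``irregularity``."""
    cy, cx = center
    aspect = rng.uniform(0.7, 1.3)
    theta0 = rng.uniform(0, 2 * np.pi)
    n_harm = 4
    amp = rng.uniform(-1, 1, n_harm) * irregularity * 0.35
    phase = rng.uniform(0, 2 * np.pi, n_harm)

    half = int(np.ceil(radius * 1.9)) + 2
    r0, c0 = int(round(cy)), int(round(cx))
    rr, cc = np.mgrid[-half:half + 1, -half:half + 1]
    # rotate into ellipse frame
    u = rr * np.cos(theta0) + cc * np.sin(theta0)
    v = -rr * np.sin(theta0) + cc * np.cos(theta0)
    dist = np.hypot(u / aspect, v * aspect)
    ang = np.arctan2(v, u)
    rad = radius * (1.0 + sum(amp[k] * np.cos((k + 2) * ang + phase[k])
                              for k in range(n_harm)))
    blob_local = dist <= np.maximum(rad, 1.0)

    blob = np.zeros((size, size), dtype=bool)
    rlo, rhi = max(r0 - half, 0), min(r0 + half + 1, size)
    clo, chi = max(c0 - half, 0), min(c0 + half + 1, size)
    blob[rlo:rhi, clo:chi] = blob_local[rlo - (r0 - half):rhi - (r0 - half),
                                        clo - (c0 - half):chi - (c0 - half)]
    return blob


def generate_phantom(config: PhantomConfig) -> PhantomSample:
    """Generate one phantom: smooth bright half-disc breast on a near-zero
    background, textured with Gaussian noise, plus ``n_masses`` brighter
    irregular elliptical masses fully inside the breast.

    Deterministic for a fixed ``config.seed``.  Raises ``RuntimeError`` if a
    mass cannot be placed inside the breast within 1000 rejection-sampling
    tries.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    size = config.image_size

    breast = _breast_mask(size, config.breast_shape, rng)
    base = np.where(breast, 0.45, 0.0)
    # radial shading so tissue is brightest near the chest wall
    rr, cc = np.mgrid[0:size, 0:size]
    if config.breast_shape == "half-disc-left":
        depth = cc / size
    else:
        depth = ((size - 1) - cc) / size
    base = base * (1.0 - 0.35 * depth)
    texture = rng.normal(0.0, config.texture_noise_sd, (size, size))
    texture = ndimage.gaussian_filter(texture, 1.2)
    image = np.where(breast, base + texture, 0.0)

    mask = np.zeros((size, size), dtype=np.uint8)
    records: list[tuple[float, float, float, str]] = []
    interior = ndimage.binary_erosion(breast, iterations=2)

    for _ in range(config.n_masses):
        radius = rng.uniform(*config.mass_radius_range)
        contrast = rng.uniform(*config.mass_contrast_range)
        placed = False
        for _try in range(1000):
            if config.place_near_edge:
                cy = rng.uniform(2, size - 3)
                cx = rng.uniform(0, radius) if config.breast_shape == "half-disc-left" \
                    else rng.uniform(size - 1 - radius, size - 1)
            else:
                cy = rng.uniform(0, size - 1)
                cx = rng.uniform(0, size - 1)
            blob = _irregular_blob(size, (cy, cx), radius,
                                   config.boundary_irregularity, rng)
            if not blob.any():
                continue
            if config.place_near_edge:
                # near-edge masses may touch the image border; only require
                # containment in the breast itself
                inside = bool(np.all(breast[blob]))
            else:
                inside = bool(np.all(interior[blob]))
            grown = ndimage.binary_dilation(blob, iterations=3)
            if inside and not (grown & (mask > 0)).any():
                placed = True
                break
        if not placed:
            raise RuntimeError("could not place mass inside breast after 1000 tries")
        # smooth additive bump: full contrast at the core, tapering at the rim
        dist_in = ndimage.distance_transform_edt(blob)
        bump = contrast * np.clip(dist_in / max(radius * 0.5, 1.0), 0.15, 1.0)
        image = image + np.where(blob, bump, 0.0)
        mask[blob] = 1
        com = ndimage.center_of_mass(blob)
        eq_radius = float(np.sqrt(blob.sum() / np.pi))
        label = "malignant" if config.boundary_irregularity > 0.5 else "benign"
        records.append((float(com[0]), float(com[1]), eq_radius, label))

    image = np.clip(image, 0.0, 1.0)
    return PhantomSample(image=image.astype(np.float64), mask=mask,
                         mass_records=records, seed=config.seed)


def _child_seed(seed: int, i: int) -> int:
    return int((seed * 1_000_003 + 7919 * i + 1) % (2 ** 31))


def generate_dataset(n: int, config: PhantomConfig,
                     out_dir: str | Path | None = None) -> list[PhantomSample]:
    """Generate ``n`` phantoms with per-sample seeds derived from
    ``config.seed``; optionally write image/mask PNG pairs plus a JSON
    manifest to ``out_dir``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples: list[PhantomSample] = []
    for i in range(n):
        n_masses = config.n_masses
        if config.n_masses_range is not None:
            lo, hi = config.n_masses_range
            n_masses = int(rng.integers(lo, hi + 1))
        sub = PhantomConfig(**{**asdict(config),
                               "n_masses": n_masses,
                               "n_masses_range": None,
                               "seed": _child_seed(config.seed, i)})
        samples.append(generate_phantom(sub))

    if out_dir is not None:
        import imageio.v3 as iio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = []
        for i, s in enumerate(samples):
            img_path = out / f"phantom_{i:04d}.png"
            msk_path = out / f"phantom_{i:04d}_mask.png"
            iio.imwrite(img_path, np.round(s.image * 65535).astype(np.uint16))
            iio.imwrite(msk_path, (s.mask * 255).astype(np.uint8))
            manifest.append({
                "image": img_path.name,
                "mask": msk_path.name,
                "seed": s.seed,
                "mass_records": [list(r) for r in s.mass_records],
            })
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return samples
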