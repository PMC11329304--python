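# Methods

## Model

`mammoseg` segments breast masses in 2-D mammograms with a two-stage
cascade. The first stage (presegmenter) is a plain U-net; in its *patch*
configuration it is trained on fixed-size windows centered on each mass
component and applied at test time to overlapping windows (stride = half
the window) tiling the whole frame. Per-window probability maps are fused
with a per-pixel maximum into a saliency map; binary masks fuse with a
logical OR. Max/OR fusion is deliberately miss-averse: a lesion detected in
any one window survives aggregation. The second stage is an Attention U-net
that consumes the image together with the saliency map. At every encoder
level `n` a presegmenter-attention (PSA) block average-pools the saliency
map to the level's spatial size, projects saliency and (post-pool) encoder
features through 1×1 convolutions with batch normalization, adds them,
derives a single-channel sigmoid attention map, and rescales every feature
channel by it:

    P_n = AvgPool2x2(P_{n-1})                      (P_0 = saliency input)
    A_n = BN(Conv1x1_{k_n}(P_n)) + BN(Conv1x1_{k_n}(F_n))
    O_n = sigmoid(Conv1x1_1(ReLU(A_n))) ⊗ F_n

The guided features `O_n` feed the next encoder level and serve as the skip
input to the matching decoder attention gate (additive attention: both
inputs projected to `k_n/2` channels, summed, ReLU, 1×1 convolution,
sigmoid, multiplied onto the skip). Because the stated PSA feature sizes
are `input_size / 2^n`, the block necessarily operates on post-pool
features; `O_n` *replaces* the conventional pre-pool skip — the one reading
of the block diagram consistent with both the feature sizes and the guided
data flow. Both stages train with Adam on the soft dice loss
`1 − 2Σp_i g_i/(Σp_i² + Σg_i² + ε)`, `ε = 1e−6`.

## Assumptions

* Masses are locally brighter than surrounding tissue and compact; the
  patch presegmenter sees each training mass centered in its window.
* One grayscale view per image; no multi-view or temporal fusion.
* Saliency maps are probabilities, never thresholded before the second
  stage, so the cascade can recover from a weak but nonzero first-stage
  response.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `levels`, `filters_per_level` | 5, (32, 64, 128, 256, 512) | encoder depth / width of the full-scale nets |
| patch size / stride | 1024 / 512 px | test-time tiling with 50% overlap (full scale) |
| presegmenter input | 256 | patches are resized to this before prediction |
| cascade input | 512 | image + saliency resized to this for stage 2 |
| learning rate / batch | 1e−4 / 2 | Adam training defaults |
| `threshold` | 0.5 | binarization of the stage-2 probability map |
| truncation percentiles | 5th / 99th | intensity window from breast-region pixels (linear-interpolation percentile rule) |
| CLAHE clip limits | 0.01, 0.02 | channels 1–2 of the three-channel input; 8×8 tile grid |

Desk-scale experiments (tests, acceptance script) shrink the same knobs:
phantoms 128², patch 128 / stride 64, presegmenter input 64, cascade input
128, 3 levels with (4, 8, 16) filters, learning rate 1e−3 (appropriate for
nets this small trained 30 epochs), 120 phantoms with a held-out fifth.
These sizes were chosen once so the whole pipeline trains in minutes on one
CPU while leaving the method itself unchanged.

## Synthetic phantoms

The generator emulates exactly the structure the cascade relies on: a
bright elliptical half-disc "breast" anchored on one image edge, smooth
radial shading plus band-limited Gaussian texture, and 0–3 brighter masses
— ellipses whose radius is jittered by low-order angular harmonics scaled
by a `boundary_irregularity` knob (irregularity > 0.5 tags the mass
"malignant", a pure pass-through label for stratified reporting). Masses
are rejection-sampled to lie fully inside the breast and not touch one
another; a `place_near_edge` flag exercises the patch-padding path
deterministically. Masks are pixel-exact by construction.

Phantoms do **not** model pectoral muscle, calcifications, annotation
noise, scanner artifacts, or realistic parenchymal texture. Passing tests
therefore demonstrates that the pipeline's geometry, training dynamics and
bookkeeping are correct and that saliency guidance helps on a learnable
task — not that clinical-grade accuracy transfers to real mammograms.

## Numerical choices

* Networks run on `mammoseg.nn`, a small reverse-mode autodiff engine on
  float32 numpy arrays (im2col + BLAS matmul convolutions; every op's
  gradient is finite-difference-checked in the test suite). Weight init is
  He-uniform from an explicit generator, so identical seeds give identical
  parameters; training is fully deterministic.
* Decoder upsampling is nearest-neighbour ×2 followed by convolution.
* Batch normalization inside conv blocks is on by default (configurable
  off); the PSA block always normalizes per branch before the addition,
  exactly as the `A_n` equation orders it.
* Foreground for orientation/cropping is Otsu's threshold (parameter-free).
  Percentiles use linear interpolation between order statistics.
  Truncation statistics come from breast-region pixels and are applied to
  the whole frame, so background stays 0.
* Image resizing is bilinear; masks use nearest-neighbour plus >0.5
  re-binarization. Overlapping-patch extraction clamps the final offset so
  the last window ends flush with the border (full coverage; interior
  pixels covered exactly 4× at 50% overlap).
* Metric conventions: ground truth and prediction both empty ⇒ dice =
  precision = recall = 1; empty prediction with nonempty truth ⇒ precision
  0 and a false-negative outcome with dice 0. The FPR denominator defaults
  to all non-mass pixels of the frame; a switch restricts it to a supplied
  breast region. Evaluation happens in original image space after the
  inverse geometry.

## Design choices where the design was open

* The second stage trains on saliency maps from a presegmenter trained on
  the same training split (per fold), never on held-out images.
* The standalone baseline is the identical Attention U-net topology with
  PSA blocks removed (skips = pooled features), trained identically — so
  the cascade comparison isolates the saliency guidance.
* Attention-gate intermediate width is half the skip channels.
* Benign/malignant stratification is reported but carries no clinical
  meaning on phantoms.

## Limitations

* The numpy engine is CPU-only and unsuited to full-resolution (512²,
  five-level) training; the architecture supports it, but practical runs at
  that scale would need hours.
* Only the Attention U-net backbone is implemented; the PSA/cascade
  interface is generic, but alternative backbones are out of scope.
* Whole-image presegmentation reuses the same U-net topology as the patch
  model; no architecture search was attempted.
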