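"""Trainable components of the cascade.

Three architectures are defined on top of :mod:`mammoseg.nn`:

* a plain U-net used as the presegmenter (patch or whole-image);
* the presegmenter-attention (PSA) block, which average-pools the saliency
  map to each encoder level's spatial size, fuses it with the encoder
  features through 1x1 convolutions + batch normalization and elementwise
  addition, derives sigmoid spatial attention coefficients, and rescales
  every feature channel by them;
* the second-stage Attention U-net whose encoder is guided by a PSA block
  at every level and whose decoder applies additive attention gates to the
  guided skip features.

Training minimizes the soft dice loss
``1 - 2*sum(p_i*g_i) / (sum(p_i^2) + sum(g_i^2) + eps)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["NetConfig", "LossInputs", "dice_loss", "PSABlock", "AttentionGate",
           "UNet", "CascadeAttentionUNet", "build_presegmenter",
           "build_cascade_segmenter", "psa_block_forward",
           "attention_gate_forward"]


@dataclass(frozen=True)
class NetConfig:
    """Architecture hyperparameters.

    Defaults follow the full-scale model: five encoder levels with 32, 64,
    128, 256 and 512 filters.  Desk-scale experiments shrink ``levels``,
    ``filters_per_level`` and ``input_size`` through the same fields.
    """

    levels: int = 5
    filters_per_level: tuple[int, ...] = (32, 64, 128, 256, 512)
    input_size: int = 512
    input_channels: int = 3
    kernel_size: int = 3
    with_psa: bool = False
    batch_norm: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if len(self.filters_per_level) != self.levels:
            raise ValueError("filters_per_level length must equal levels")
        if self.input_size % (2 ** self.levels) != 0:
            raise ValueError("input_size must be divisible by 2**levels")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")

    def to_yaml(self) -> str:
        import yaml

        d = dataclasses.asdict(self)
        d["filters_per_level"] = list(d["filters_per_level"])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "NetConfig":
        import yaml

        d = yaml.safe_load(text)
        d["filters_per_level"] = tuple(d["filters_per_level"])
        return cls(**d)


@dataclass
class LossInputs:
    p: np.ndarray
    g: np.ndarray
    epsilon: float = 1e-6


def dice_loss(p, g=None, eps: float = 1e-6) -> float:
    """Soft dice loss over flattened prediction/ground-truth arrays.

    Accepts either ``dice_loss(LossInputs(...))`` or ``dice_loss(p, g, eps)``.
    Returns ``1 - 2*sum(p*g) / (sum(p^2) + sum(g^2) + eps)``, in [0, 1];
    the all-zero/all-zero case evaluates to 1 by the 0/eps convention.
    """
    if isinstance(p, LossInputs):
        p, g, eps = p.p, p.g, p.epsilon
    if eps <= 0:
        raise ValueError("eps must be positive")
    p = np.asarray(p, dtype=np.float64).ravel()
    g = np.asarray(g, dtype=np.float64).ravel()
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    num = 2.0 * float(p @ g)
    den = float(p @ p) + float(g @ g) + eps
    return 1.0 - num / den


def _to_tensor(arr: np.ndarray) -> Tensor:
    """HWC / HW / BCHW numpy -> (B, C, H, W) Tensor."""
    a = np.asarray(arr, dtype=np.float32)
    if a.ndim == 2:
        a = a[None, None]
    elif a.ndim == 3:
        a = a.transpose(2, 0, 1)[None]
    elif a.ndim != 4:
        raise ValueError(f"cannot interpret array of ndim {a.ndim}")
    return Tensor(a)


class PSABlock(nn.Module):
    """Presegmenter attention at one encoder level (channel count k)."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv_p = nn.Conv2d(1, channels, 1, rng)
        self.bn_p = nn.BatchNorm2d(channels)
        self.conv_f = nn.Conv2d(channels, channels, 1, rng)
        self.bn_f = nn.BatchNorm2d(channels)
        self.conv_a = nn.Conv2d(channels, 1, 1, rng)

    def __call__(self, p_prev: Tensor, f_n: Tensor):
        """Returns ``(o_n, p_n, coefficients)``.

        ``p_prev`` (B,1,2s,2s) is average-pooled to ``p_n`` (B,1,s,s); the
        fused descriptor is ``A = BN(conv1x1(p_n)) + BN(conv1x1(f_n))``;
        coefficients are ``sigmoid(conv1x1(relu(A)))`` and the output is
        their channel-wise product with ``f_n``.
        """
        p_n = nn.avgpool2(p_prev)
        if p_n.shape[2:] != f_n.shape[2:]:
            raise ValueError(
                f"saliency {p_n.shape[2:]} does not align with features "
                f"{f_n.shape[2:]} after pooling")
        a_n = nn.add(self.bn_p(self.conv_p(p_n)), self.bn_f(self.conv_f(f_n)))
        coeff = nn.sigmoid(self.conv_a(nn.relu(a_n)))
        o_n = nn.mul_coeff(coeff, f_n)
        return o_n, p_n, coeff


class AttentionGate(nn.Module):
    """Additive attention on a skip connection (gating at same resolution)."""

    def __init__(self, skip_channels: int, gating_channels: int,
                 rng: np.random.Generator, inter_channels: int | None = None):
        super().__init__()
        inter = inter_channels or max(skip_channels // 2, 1)
        self.theta = nn.Conv2d(skip_channels, inter, 1, rng)
        self.phi = nn.Conv2d(gating_channels, inter, 1, rng)
        self.psi = nn.Conv2d(inter, 1, 1, rng)

    def __call__(self, gating: Tensor, skip: Tensor) -> Tensor:
        if gating.shape[2:] != skip.shape[2:]:
            raise ValueError("gating and skip must share spatial dimensions")
        a = nn.relu(nn.add(self.theta(skip), self.phi(gating)))
        coeff = nn.sigmoid(self.psi(a))
        return nn.mul_coeff(coeff, skip)


class UNet(nn.Module):
    """Plain U-net: `levels` encoder stages (two 3x3 convs each, 2x2 pool
    between), symmetric decoder with skip concatenation, 1x1 sigmoid head."""

    def __init__(self, config: NetConfig):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        f = list(config.filters_per_level)
        L = config.levels
        self.enc = []
        in_ch = config.input_channels
        for n in range(L):
            self.enc.append(nn.ConvBlock(in_ch, f[n], rng, config.kernel_size,
                                         config.batch_norm))
            in_ch = f[n]
        self.bottleneck = nn.ConvBlock(f[-1], f[-1], rng, config.kernel_size,
                                       config.batch_norm)
        self.dec = []
        d_ch = f[-1]
        for n in range(L - 1, -1, -1):
            self.dec.append(nn.ConvBlock(d_ch + f[n], f[n], rng,
                                         config.kernel_size, config.batch_norm))
            d_ch = f[n]
        self.head = nn.Conv2d(f[0], 1, 1, rng)

    def forward(self, image: Tensor) -> Tensor:
        skips = []
        h = image
        for block in self.enc:
            c = block(h)
            skips.append(c)
            h = nn.maxpool2(c)
        d = self.bottleneck(h)
        for i, block in enumerate(self.dec):
            d = nn.upsample2(d)
            d = block(nn.concat_channels(d, skips[-(i + 1)]))
        return nn.sigmoid(self.head(d))

    def predict(self, image: np.ndarray) -> np.ndarray:
        """HWC (or batch) image in [0,1] -> 2-D probability map."""
        self.eval()
        with nn.no_grad():
            out = self.forward(_to_tensor(image))
        self.train()
        return out.data[0, 0].astype(np.float64)


class CascadeAttentionUNet(nn.Module):
    """Attention U-net, optionally guided by a presegmenter saliency map.

    With ``with_psa=True`` each encoder level's post-pool features pass
    through a PSA block fed by the progressively pooled saliency map; the
    guided features feed the next encoder level and serve as the skip into
    the matching decoder attention gate.  With ``with_psa=False`` the same
    topology runs on the raw pooled features (the standalone baseline).
    """

    def __init__(self, config: NetConfig):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        f = list(config.filters_per_level)
        L = config.levels
        self.with_psa = config.with_psa
        self.enc = []
        self.psa = []
        in_ch = config.input_channels
        for n in range(L):
            self.enc.append(nn.ConvBlock(in_ch, f[n], rng, config.kernel_size,
                                         config.batch_norm))
            if self.with_psa:
                self.psa.append(PSABlock(f[n], rng))
            in_ch = f[n]
        self.bottleneck = nn.ConvBlock(f[-1], f[-1], rng, config.kernel_size,
                                       config.batch_norm)
        self.gates = []
        self.dec = []
        d_ch = f[-1]
        for n in range(L - 1, -1, -1):
            self.gates.append(AttentionGate(f[n], d_ch, rng))
            self.dec.append(nn.ConvBlock(d_ch + f[n], f[n], rng,
                                         config.kernel_size, config.batch_norm))
            d_ch = f[n]
        self.head = nn.Conv2d(f[0], 1, 1, rng)

    def forward(self, image: Tensor, saliency: Tensor | None = None) -> Tensor:
        if self.with_psa and saliency is None:
            raise ValueError("PSA model requires a saliency input")
        skips = []
        h = image
        p = saliency
        for n, block in enumerate(self.enc):
            c = block(h)
            pooled = nn.maxpool2(c)
            if self.with_psa:
                o_n, p, _ = self.psa[n](p, pooled)
            else:
                o_n = pooled
            skips.append(o_n)
            h = o_n
        d = self.bottleneck(h)
        for i, (gate, block) in enumerate(zip(self.gates, self.dec)):
            skip = skips[-(i + 1)]
            att = gate(d, skip)
            d = block(nn.concat_channels(d, att))
            d = nn.upsample2(d)
        return nn.sigmoid(self.head(d))

    def predict(self, image: np.ndarray,
                saliency: np.ndarray | None = None) -> np.ndarray:
        self.eval()
        with nn.no_grad():
            sal = None if saliency is None else _to_tensor(saliency)
            out = self.forward(_to_tensor(image), sal)
        self.train()
        return out.data[0, 0].astype(np.float64)


def build_presegmenter(config: NetConfig) -> UNet:
    """Plain U-net presegmenter (patch or whole-image)."""
    if config.with_psa:
        raise ValueError("presegmenter must have with_psa=False")
    return UNet(config)


def build_cascade_segmenter(config: NetConfig) -> CascadeAttentionUNet:
    """PSA-guided Attention U-net second stage."""
    if not config.with_psa:
        raise ValueError("cascade segmenter requires with_psa=True")
    return CascadeAttentionUNet(config)


def psa_block_forward(p_prev: np.ndarray, f_n: np.ndarray,
                      weights: PSABlock):
    """Functional PSA forward on numpy grids.

    ``p_prev``: (2s, 2s) saliency; ``f_n``: (s, s, k) features.  Returns
    ``(o_n (s, s, k), p_n (s, s))``.
    """
    p_t = _to_tensor(np.asarray(p_prev)[..., None] if np.asarray(p_prev).ndim == 2
                     else p_prev)
    f_t = _to_tensor(f_n)
    with nn.no_grad():
        o_n, p_n, _ = weights(p_t, f_t)
    return (o_n.data[0].transpose(1, 2, 0).astype(np.float64),
            p_n.data[0, 0].astype(np.float64))


def attention_gate_forward(gating: np.ndarray, skip: np.ndarray,
                           weights: AttentionGate) -> np.ndarray:
    """Functional attention-gate forward on (s, s, c) numpy grids."""
    with nn.no_grad():
        out = weights(_to_tensor(gating), _to_tensor(skip))
    return out.data[0].transpose(1, 2, 0).astype(np.float64)
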