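"""Minimal reverse-mode automatic differentiation on numpy arrays.

Tensors are float32 NCHW arrays wrapped with a gradient slot and a backward
closure; calling :meth:`Tensor.backward` on a scalar loss walks the tape in
reverse topological order.  Only the operations the segmentation networks
need are provided: same-padding convolution, batch normalization, 2x2
max/average pooling, nearest-neighbour x2 upsampling, relu/sigmoid,
channel concatenation, elementwise add and coefficient-map multiplication,
and a soft dice loss.  Every op's gradient is exercised by finite-difference
checks in the test suite.
"""

from __future__ import annotations

import contextlib

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

__all__ = [
    "Tensor", "no_grad", "is_grad_enabled",
    "add", "mul_coeff", "relu", "sigmoid", "concat_channels",
    "conv2d", "batchnorm2d", "maxpool2", "avgpool2", "upsample2",
    "dice_loss_tensor",
]

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable tape construction (inference mode)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward_fn=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward_fn = backward_fn

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float32)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward_fn is not None and node.grad is not None:
                node._backward_fn(node.grad)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _needs_grad(t: "Tensor") -> bool:
    return t.requires_grad or bool(t._parents)


def _make(data, parents, backward_fn):
    if is_grad_enabled() and any(_needs_grad(p) for p in parents):
        return Tensor(data, parents=parents, backward_fn=backward_fn)
    return Tensor(data)


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    out_data = a.data + b.data

    def bwd(g):
        a.accumulate(g)
        b.accumulate(g)

    return _make(out_data, (a, b), bwd)


def mul_coeff(coeff: Tensor, x: Tensor) -> Tensor:
    """Broadcast a (B,1,H,W) coefficient map over the channels of x."""
    if coeff.shape[0] != x.shape[0] or coeff.shape[2:] != x.shape[2:] \
            or coeff.shape[1] != 1:
        raise ValueError(f"coefficient shape {coeff.shape} incompatible with {x.shape}")
    out_data = coeff.data * x.data

    def bwd(g):
        coeff.accumulate((g * x.data).sum(axis=1, keepdims=True))
        x.accumulate(g * coeff.data)

    return _make(out_data, (coeff, x), bwd)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0.0)

    def bwd(g):
        x.accumulate(g * mask)

    return _make(out_data, (x,), bwd)


def sigmoid(x: Tensor) -> Tensor:
    s = expit(x.data)

    def bwd(g):
        x.accumulate(g * s * (1.0 - s))

    return _make(s, (x,), bwd)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    if a.shape[0] != b.shape[0] or a.shape[2:] != b.shape[2:]:
        raise ValueError(f"cannot concat {a.shape} with {b.shape}")
    ca = a.shape[1]
    out_data = np.concatenate([a.data, b.data], axis=1)

    def bwd(g):
        a.accumulate(g[:, :ca])
        b.accumulate(g[:, ca:])

    return _make(out_data, (a, b), bwd)


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Stride-1 same-padding 2-D convolution (odd square kernels).

    x: (B, C, H, W); w: (F, C, k, k); b: (F,).
    """
    B, C, H, W = x.shape
    F, Cw, kh, kw = w.shape
    if Cw != C:
        raise ValueError(f"conv channel mismatch: input {C}, kernel {Cw}")
    ph, pw = kh // 2, kw // 2
    if kh == 1 and kw == 1:
        w2 = w.data.reshape(F, C)
        out_data = np.matmul(w2, x.data.reshape(B, C, H * W)).reshape(B, F, H, W) \
            + b.data[None, :, None, None]

        def bwd(g):
            gm = g.reshape(B, F, H * W)
            xm = x.data.reshape(B, C, H * W)
            b.accumulate(g.sum(axis=(0, 2, 3)))
            dw = np.matmul(gm, xm.transpose(0, 2, 1)).sum(axis=0)
            w.accumulate(dw.reshape(F, C, 1, 1))
            if _needs_grad(x):
                x.accumulate(np.matmul(w2.T, gm).reshape(B, C, H, W))

        return _make(out_data, (x, w, b), bwd)

    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # B,C,H,W,kh,kw
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)) \
        .reshape(B * H * W, C * kh * kw)
    wmat = w.data.reshape(F, -1)
    out_data = (cols @ wmat.T).reshape(B, H, W, F).transpose(0, 3, 1, 2) \
        + b.data[None, :, None, None]

    def bwd(g):
        gm = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(B * H * W, F)
        b.accumulate(g.sum(axis=(0, 2, 3)))
        w.accumulate((gm.T @ cols).reshape(F, C, kh, kw))
        if not _needs_grad(x):
            return
        # dx = full correlation of g with the spatially flipped kernel,
        # computed with the same im2col + matmul machinery
        gp = np.pad(g, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        gwin = sliding_window_view(gp, (kh, kw), axis=(2, 3))
        gcols = np.ascontiguousarray(gwin.transpose(0, 2, 3, 1, 4, 5)) \
            .reshape(B * H * W, F * kh * kw)
        wflip = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # C,F,kh,kw
        dx = (gcols @ wflip.reshape(C, -1).T).reshape(B, H, W, C) \
            .transpose(0, 3, 1, 2)
        x.accumulate(dx)

    return _make(out_data, (x, w, b), bwd)


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                running_mean: np.ndarray, running_var: np.ndarray,
                training: bool, momentum: float = 0.1,
                eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization; running stats updated in place."""
    B, C, H, W = x.shape
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    std = np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) / std[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def bwd(g):
        gamma.accumulate((g * xhat).sum(axis=(0, 2, 3)))
        beta.accumulate(g.sum(axis=(0, 2, 3)))
        gs = g * gamma.data[None, :, None, None]
        if training:
            mean_gs = gs.mean(axis=(0, 2, 3), keepdims=True)
            mean_gs_xhat = (gs * xhat).mean(axis=(0, 2, 3), keepdims=True)
            dx = (gs - mean_gs - xhat * mean_gs_xhat) / std[None, :, None, None]
        else:
            dx = gs / std[None, :, None, None]
        x.accumulate(dx)

    return _make(out_data, (x, gamma, beta), bwd)


def _to_blocks(a: np.ndarray) -> np.ndarray:
    B, C, H, W = a.shape
    return a.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5) \
            .reshape(B, C, H // 2, W // 2, 4)


def maxpool2(x: Tensor) -> Tensor:
    B, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {H}x{W}")
    blocks = _to_blocks(x.data)
    arg = blocks.argmax(axis=-1)
    out_data = np.take_along_axis(blocks, arg[..., None], axis=-1)[..., 0]

    def bwd(g):
        gb = np.zeros_like(blocks)
        np.put_along_axis(gb, arg[..., None], g[..., None], axis=-1)
        dx = gb.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5) \
               .reshape(B, C, H, W)
        x.accumulate(dx)

    return _make(out_data, (x,), bwd)


def avgpool2(x: Tensor) -> Tensor:
    B, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError(f"avgpool2 needs even spatial dims, got {H}x{W}")
    out_data = _to_blocks(x.data).mean(axis=-1)

    def bwd(g):
        dx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
        x.accumulate(dx)

    return _make(out_data, (x,), bwd)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour x2 spatial upsampling."""
    out_data = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def bwd(g):
        B, C, H2, W2 = g.shape
        dx = g.reshape(B, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5))
        x.accumulate(dx)

    return _make(out_data, (x,), bwd)


def dice_loss_tensor(p: Tensor, g: np.ndarray, eps: float = 1e-6) -> Tensor:
    """Soft dice loss 1 - 2*sum(p*g) / (sum(p^2) + sum(g^2) + eps) over all
    elements of the batch; differentiable in p."""
    gt = np.asarray(g, dtype=np.float32)
    if gt.shape != p.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {gt.shape}")
    num = 2.0 * float((p.data * gt).sum())
    den = float((p.data ** 2).sum() + (gt ** 2).sum()) + eps
    loss = 1.0 - num / den

    def bwd(gout):
        scale = float(gout.reshape(-1)[0])
        dp = 2.0 * (num * p.data - gt * den) / (den * den)
        p.accumulate(scale * dp)

    return _make(np.float32(loss), (p,), bwd)
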