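"""Layer/module containers over the autodiff ops, plus Adam.

Weight initialization is He-uniform driven by an explicit
``numpy.random.Generator``, so two builds from the same seed carry
bit-identical parameters.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["Parameter", "Module", "Conv2d", "BatchNorm2d", "ConvBlock", "Adam"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base container: recursive parameter collection and train/eval mode."""

    def __init__(self):
        self.training = True

    def modules(self):
        out = []
        for v in self.__dict__.values():
            items = v if isinstance(v, (list, tuple)) else [v]
            for item in items:
                if isinstance(item, Module):
                    out.append(item)
                    out.extend(item.modules())
        return out

    def parameters(self) -> list[Parameter]:
        params = []
        for mod in [self] + self.modules():
            for v in mod.__dict__.values():
                items = v if isinstance(v, (list, tuple)) else [v]
                params.extend(p for p in items if isinstance(p, Parameter))
        return params

    def train(self):
        for mod in [self] + self.modules():
            mod.training = True
        return self

    def eval(self):
        for mod in [self] + self.modules():
            mod.training = False
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, p in enumerate(self.parameters()):
            state[f"param_{i}"] = p.data
        for j, mod in enumerate([self] + self.modules()):
            if isinstance(mod, BatchNorm2d):
                state[f"bn_{j}_mean"] = mod.running_mean
                state[f"bn_{j}_var"] = mod.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data = np.array(state[f"param_{i}"], dtype=np.float32)
        for j, mod in enumerate([self] + self.modules()):
            if isinstance(mod, BatchNorm2d):
                mod.running_mean = np.array(state[f"bn_{j}_mean"], dtype=np.float32)
                mod.running_var = np.array(state[f"bn_{j}_var"], dtype=np.float32)

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files})


def he_uniform(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / max(fan_in, 1))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv2d(Module):
    """Stride-1 same-padding convolution with odd square kernel."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        super().__init__()
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(he_uniform(
            rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return ad.batchnorm2d(x, self.gamma, self.beta, self.running_mean,
                              self.running_var, self.training,
                              self.momentum, self.eps)


class ConvBlock(Module):
    """(3x3 conv [+ BN] + relu) x 2, the standard U-net stage block."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator, kernel_size: int = 3,
                 batch_norm: bool = True):
        super().__init__()
        self.conv1 = Conv2d(in_channels, out_channels, kernel_size, rng)
        self.conv2 = Conv2d(out_channels, out_channels, kernel_size, rng)
        self.bn1 = BatchNorm2d(out_channels) if batch_norm else None
        self.bn2 = BatchNorm2d(out_channels) if batch_norm else None

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv1(x)
        if self.bn1 is not None:
            h = self.bn1(h)
        h = ad.relu(h)
        h = self.conv2(h)
        if self.bn2 is not None:
            h = self.bn2(h)
        return ad.relu(h)


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
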