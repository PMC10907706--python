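"""Layer/module abstraction over the autodiff core.

Mirrors the familiar Module API: parameters are discovered by attribute
traversal, ``train()``/``eval()`` toggle batch-norm statistics, and
``state_dict``/``load_state_dict`` serialize to flat name->array mappings.
"""

from __future__ import annotations

import math

import numpy as np

from . import functional as F
from .tensor import Parameter, Tensor

__all__ = [
    "Module",
    "Sequential",
    "Conv2d",
    "ConvTranspose2d",
    "Linear",
    "BatchNorm2d",
    "LayerNorm",
    "MaxPool2d",
    "GELU",
    "ReLU",
    "Sigmoid",
    "MultiheadSelfAttention",
    "seed_all",
]

_rng = np.random.default_rng(0)


def seed_all(seed: int) -> None:
    """Reset the global RNG used for parameter initialization."""
    global _rng
    _rng = np.random.default_rng(seed)


def trunc_normal(shape, std: float = 0.02) -> np.ndarray:
    x = _rng.standard_normal(shape) * std
    return np.clip(x, -2 * std, 2 * std).astype(np.float32)


def kaiming_uniform(shape, fan_in: int) -> np.ndarray:
    bound = math.sqrt(1.0 / fan_in)
    return _rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Module:
    def __init__(self):
        self.training = True

    # -- traversal ---------------------------------------------------------
    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, v in enumerate(val):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def _buffers(self, prefix: str = ""):
        for name in getattr(self, "_buffer_names", ()):
            yield prefix + name, getattr(self, name)
        for name, child in self._children():
            yield from child._buffers(prefix + name + ".")

    def train(self):
        self.training = True
        for _, c in self._children():
            c.train()
        return self

    def eval(self):
        self.training = False
        for _, c in self._children():
            c.eval()
        return self

    # -- serialization -----------------------------------------------------
    def state_dict(self) -> dict:
        d = {name: p.data.copy() for name, p in self.named_parameters()}
        d.update({name: b.copy() for name, b in self._buffers()})
        return d

    def load_state_dict(self, d: dict) -> None:
        params = dict(self.named_parameters())
        for name, arr in d.items():
            if name in params:
                if params[name].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name}")
                params[name].data = arr.astype(np.float32).copy()
            else:
                obj, attr = self._resolve(name)
                setattr(obj, attr, arr.copy())

    def _resolve(self, dotted: str):
        obj = self
        parts = dotted.split(".")
        for p in parts[:-1]:
            obj = obj[int(p)] if p.isdigit() else getattr(obj, p)
        return obj, parts[-1]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def __getitem__(self, i):
        return self.mods[i]

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel_size: int, padding: int = 0,
                 bias: bool = True, zero_init: bool = False):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel_size, self.padding = kernel_size, padding
        fan_in = in_ch * kernel_size * kernel_size
        shape = (out_ch, in_ch, kernel_size, kernel_size)
        self.weight = Parameter(
            np.zeros(shape, np.float32) if zero_init else kaiming_uniform(shape, fan_in)
        )
        self.bias = Parameter(
            np.zeros(out_ch, np.float32) if zero_init else kaiming_uniform((out_ch,), fan_in)
        ) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, padding=self.padding)


class ConvTranspose2d(Module):
    """Kernel-2 stride-2 transposed convolution (exact x2 upsampler)."""

    def __init__(self, in_ch: int, out_ch: int):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        fan_in = in_ch  # each output position sees one input position per channel
        self.weight = Parameter(kaiming_uniform((in_ch, out_ch, 2, 2), fan_in))
        self.bias = Parameter(kaiming_uniform((out_ch,), fan_in))

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose2d_2x2(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, bias: bool = True, std: float = 0.02,
                 zero_init: bool = False):
        super().__init__()
        self.in_f, self.out_f = in_f, out_f
        self.weight = Parameter(
            np.zeros((in_f, out_f), np.float32) if zero_init
            else trunc_normal((in_f, out_f), std)
        )
        self.bias = Parameter(np.zeros(out_f, np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class BatchNorm2d(Module):
    _buffer_names = ("running_mean", "running_var")

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.channels, self.eps, self.momentum = channels, eps, momentum
        self.gamma = Parameter(np.ones(channels, np.float32))
        self.beta = Parameter(np.zeros(channels, np.float32))
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)

    def forward(self, x: Tensor) -> Tensor:
        c = self.channels
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (
                mu.data.reshape(c) - self.running_mean
            )
            self.running_var += self.momentum * (
                var.data.reshape(c) - self.running_var
            )
            inv = (var + self.eps) ** -0.5
            xn = xc * inv
        else:
            mu = self.running_mean.reshape(1, c, 1, 1)
            inv = 1.0 / np.sqrt(self.running_var.reshape(1, c, 1, 1) + self.eps)
            xn = (x - mu) * inv
        return xn * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.dim, self.eps = dim, eps
        self.gamma = Parameter(np.ones(dim, np.float32))
        self.beta = Parameter(np.zeros(dim, np.float32))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps) ** -0.5 * self.gamma + self.beta


class MaxPool2d(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.max_pool2d(x)


class GELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.gelu()


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class MultiheadSelfAttention(Module):
    """Standard multi-head self-attention over (B, N, D) token sequences."""

    def __init__(self, dim: int, heads: int):
        super().__init__()
        if dim % heads:
            raise ValueError(f"embedding dim {dim} not divisible by {heads} heads")
        self.dim, self.heads, self.head_dim = dim, heads, dim // heads
        self.qkv = Linear(dim, 3 * dim)
        self.proj = Linear(dim, dim)

    def forward(self, x: Tensor) -> Tensor:
        B, N, D = x.shape
        h, dh = self.heads, self.head_dim
        qkv = self.qkv(x).reshape(B, N, 3, h, dh).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # (B, h, N, dh)
        att = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh))
        att = att.softmax(axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(B, N, D)
        return self.proj(out)
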