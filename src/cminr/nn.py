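"""Small neural-network layer library over :mod:`cminr.autodiff`.

Provides the layers the registration models are assembled from: dense
layers, 3D convolutions (im2col), layer normalisation, multi-head
self-attention, and an Adam optimizer.  Parameter initialisation is fully
seeded; every module takes a ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .ops import unfold3d

__all__ = [
    "Module",
    "Linear",
    "Conv3d",
    "LayerNorm",
    "MultiHeadSelfAttention",
    "Adam",
    "softmax",
]


class Module:
    """Base class; tracks parameters registered as Tensor attributes."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for k, v in self.__dict__.items():
            if k.startswith("_"):  # caches/buffers are not parameters
                continue
            for p in _collect(v):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_vector(self) -> np.ndarray:
        return np.concatenate([p.data.ravel() for p in self.parameters()])

    def load_state_vector(self, vec: np.ndarray):
        i = 0
        for p in self.parameters():
            n = p.data.size
            p.data = vec[i : i + n].reshape(p.shape).copy()
            i += n
        if i != vec.size:
            raise ValueError("state vector size mismatch")


def _collect(v):
    if isinstance(v, Tensor) and v.requires_grad:
        yield v
    elif isinstance(v, Module):
        yield from v.parameters()
    elif isinstance(v, (list, tuple)):
        for item in v:
            yield from _collect(item)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            bound = 1.0 / np.sqrt(n_in)
            w = rng.uniform(-bound, bound, size=(n_in, n_out))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv3d(Module):
    """3D convolution on (C,H,W,D) tensors via im2col."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, pad: int | None = None, weight_scale: float | None = None):
        self.kernel = kernel
        self.stride = stride
        self.pad = kernel // 2 if pad is None else pad
        fan_in = c_in * kernel**3
        scale = weight_scale if weight_scale is not None else 1.0 / np.sqrt(fan_in)
        self.weight = Tensor(
            rng.uniform(-scale, scale, size=(fan_in, c_out)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.c_in, self.c_out = c_in, c_out

    def out_shape(self, spatial):
        k, s, p = self.kernel, self.stride, self.pad
        return tuple((n + 2 * p - k) // s + 1 for n in spatial)

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[0] != self.c_in:
            raise ValueError(f"expected {self.c_in} input planes, got {x.shape[0]}")
        spatial = self.out_shape(x.shape[1:])
        cols = unfold3d(x, self.kernel, self.stride, self.pad)  # (L, fan_in)
        out = cols @ self.weight + self.bias  # (L, c_out)
        return out.transpose((1, 0)).reshape((self.c_out,) + spatial)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xhat = xc / (var + self.eps).sqrt()
        return xhat * self.gamma + self.beta


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - np.max(x.data, axis=axis, keepdims=True)  # detached max
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


class MultiHeadSelfAttention(Module):
    """Standard multi-head self-attention over (n_tokens, dim) sequences."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.dh = dim // n_heads
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.out = Linear(dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        n, dim = x.shape
        heads = []
        q, k, v = self.q(x), self.k(x), self.v(x)
        for h in range(self.n_heads):
            sl = slice(h * self.dh, (h + 1) * self.dh)
            qh, kh, vh = q[:, sl], k[:, sl], v[:, sl]
            att = softmax((qh @ kh.T) * (1.0 / np.sqrt(self.dh)), axis=-1)
            heads.append(att @ vh)
        return self.out(ad.concatenate(heads, axis=1))


class Adam:
    """Adam optimizer; state can be reset to keep meta inner loops independent."""

    def __init__(self, params: list[Tensor], lr: float = 1e-5,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.reset_state()

    def reset_state(self):
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
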