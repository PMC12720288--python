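"""SIREN INR template, its modulators, and coordinate machinery.

The template is a sinusoidal MLP with an input layer, three modulated
hidden layers and a linear output head:

    F0   = sin(omega0 * (w_i v + b_i))
    F_l  = sin(gamma_l * (w_l F_{l-1}) + beta_l * b_l),   l = 1, 2, 3
    out  = w_o F3 + b_o                                   (no activation)

Note that ``beta_l`` multiplies the bias (not a FiLM-style additive
shift); a FiLM variant is available for ablation via ``film=True`` on
:func:`siren_forward`.  Modulation of all-ones reproduces the plain SIREN
bit-for-bit.  Displacement outputs are in full-resolution voxel units, so
upsampling a coarse prediction needs no value rescaling.

Widths are given as ``(d_in, h, h, h, d_out)``; the three hidden widths
must be equal (the published layout uses 256; desk-scale configs shrink
it).  ``omega0`` defaults to the standard SIREN value 30.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Conv3d, LayerNorm, Linear, Module, MultiHeadSelfAttention

__all__ = [
    "INRTemplate",
    "Modulation",
    "TokenModulator",
    "CNNModulator",
    "CoordinateGrid",
    "init_template",
    "siren_forward",
    "coordinate_grid",
]


@dataclass
class Modulation:
    """Per-hidden-layer coefficient vectors, one modulation per case."""

    gammas: list  # 3 vectors (Tensor or ndarray), each of the hidden width
    betas: list

    def __post_init__(self):
        if len(self.gammas) != 3 or len(self.betas) != 3:
            raise ValueError("modulation needs coefficients for 3 hidden layers")

    @classmethod
    def ones(cls, hidden_width: int) -> "Modulation":
        return cls(
            [np.ones(hidden_width) for _ in range(3)],
            [np.ones(hidden_width) for _ in range(3)],
        )

    def detached(self) -> "Modulation":
        def d(v):
            return v.data.copy() if isinstance(v, Tensor) else np.asarray(v).copy()

        return Modulation([d(g) for g in self.gammas], [d(b) for b in self.betas])


class INRTemplate(Module):
    """SIREN template parameters Phi = {(w_i,b_i), (w_l,b_l)_1..3, (w_o,b_o)}."""

    def __init__(self, widths=(3, 256, 256, 256, 3), omega0: float = 30.0,
                 rng: np.random.Generator | None = None):
        widths = tuple(int(w) for w in widths)
        if len(widths) != 5:
            raise ValueError("widths must be (d_in, h, h, h, d_out)")
        if len(set(widths[1:4])) != 1:
            raise ValueError("the three hidden widths must be equal")
        if rng is None:
            rng = np.random.default_rng(0)
        self.widths = widths
        self.omega0 = float(omega0)
        d_in, h, _, _, d_out = widths

        def uniform(shape, bound):
            return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)

        # SIREN initialisation: first layer +-1/fan_in, later +-sqrt(6/fan_in)/w0
        self.w_i = uniform((d_in, h), 1.0 / d_in)
        self.b_i = uniform(h, 1.0 / d_in)
        bound_h = np.sqrt(6.0 / h) / self.omega0
        self.w_h = [uniform((h, h), bound_h) for _ in range(3)]
        self.b_h = [uniform(h, bound_h) for _ in range(3)]
        self.w_o = uniform((h, d_out), bound_h)
        self.b_o = uniform(d_out, bound_h)

    @property
    def hidden_width(self) -> int:
        return self.widths[1]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())


def init_template(widths=(3, 256, 256, 256, 3), omega0: float = 30.0,
                  seed: int = 0) -> INRTemplate:
    """Seeded SIREN template construction."""
    return INRTemplate(widths, omega0, np.random.default_rng(seed))


def siren_forward(template: INRTemplate, modulation: Modulation | None,
                  coords, film: bool = False) -> Tensor:
    """Modulated SIREN forward pass: coords (N, 3) -> displacements (N, 3).

    ``modulation=None`` means the identity (all-ones) modulation.  With
    ``film=True`` the betas act as additive shifts instead of bias scalings.
    """
    x = Tensor.as_tensor(coords)
    if x.ndim != 2 or x.shape[1] != template.widths[0]:
        raise ValueError(
            f"coords must be (N, {template.widths[0]}), got {x.shape}"
        )
    f = ((x @ template.w_i + template.b_i) * template.omega0).sin()
    for layer in range(3):
        pre = f @ template.w_h[layer]
        if modulation is None:
            f = (pre + template.b_h[layer]).sin()
        else:
            gamma = Tensor.as_tensor(modulation.gammas[layer])
            beta = Tensor.as_tensor(modulation.betas[layer])
            if gamma.shape[-1] != template.hidden_width:
                raise ValueError("modulation width does not match hidden width")
            if film:
                f = (gamma * pre + template.b_h[layer] + beta).sin()
            else:
                f = (gamma * pre + beta * template.b_h[layer]).sin()
    return f @ template.w_o + template.b_o


@dataclass
class CoordinateGrid:
    """Downsampled voxel-coordinate grid normalised to [-1, 1]^3.

    ``ceil(shape/downsample)`` nodes per axis, evenly spanning the full grid
    so corner nodes sit exactly at +-1 (index 0 -> -1, index N-1 -> +1);
    this matches the align-corners convention of the trilinear upsampler.
    Coordinates are laid out row-major (C order, z fastest).
    """

    source_shape: tuple
    downsample: tuple
    coarse_shape: tuple
    coords: np.ndarray  # (prod(coarse_shape), 3)


def coordinate_grid(shape, downsample=2) -> CoordinateGrid:
    shape = tuple(int(n) for n in shape)
    if np.isscalar(downsample):
        downsample = (downsample,) * 3
    downsample = tuple(int(d) for d in downsample)
    if any(d < 1 for d in downsample):
        raise ValueError("downsample factors must be >= 1")
    coarse = tuple(int(np.ceil(n / d)) for n, d in zip(shape, downsample))
    axes = [np.linspace(-1.0, 1.0, c) if c > 1 else np.zeros(1) for c in coarse]
    mesh = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([m.ravel() for m in mesh], axis=1)
    return CoordinateGrid(shape, downsample, coarse, coords)


class _Generator(Module):
    """Two-layer perceptron emitting (gamma, beta) = (1 + dgamma, 1 + dbeta).

    The final layer is zero-initialised so the modulation is exactly the
    identity before any training."""

    def __init__(self, in_dim: int, hidden: int, width: int,
                 rng: np.random.Generator):
        self.fc1 = Linear(in_dim, hidden, rng)
        self.fc2 = Linear(hidden, 2 * width, rng, zero_init=True)
        self.width = width

    def __call__(self, ctx: Tensor):
        h = self.fc1(ctx.reshape(1, -1)).leaky_relu(0.2)
        out = self.fc2(h).reshape(-1)
        dgamma = out[: self.width]
        dbeta = out[self.width :]
        return 1.0 + dgamma, 1.0 + dbeta


class TokenModulator(Module):
    """Token-aware modulator: patch tokens -> transformer encoder block ->
    token attention with mean pooling -> three coefficient generators."""

    def __init__(self, grid_shape, hidden_width: int, token_dim: int = 192,
                 n_heads: int = 4, patch_size=(4, 4, 4), gen_hidden: int = 64,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.grid_shape = tuple(int(n) for n in grid_shape)
        self.patch_size = tuple(int(p) for p in patch_size)
        if any(n % p for n, p in zip(self.grid_shape, self.patch_size)):
            raise ValueError(
                f"grid {self.grid_shape} not divisible by patches {self.patch_size}"
            )
        if token_dim % n_heads:
            raise ValueError("token_dim must be divisible by n_heads")
        self.token_dim = token_dim
        p = self.patch_size
        self.embed = Linear(6 * p[0] * p[1] * p[2], token_dim, rng)
        self.ln1 = LayerNorm(token_dim)
        self.attn = MultiHeadSelfAttention(token_dim, n_heads, rng)
        self.ln2 = LayerNorm(token_dim)
        self.mlp1 = Linear(token_dim, 2 * token_dim, rng)
        self.mlp2 = Linear(2 * token_dim, token_dim, rng)
        self.ln3 = LayerNorm(token_dim)
        self.token_attn = MultiHeadSelfAttention(token_dim, n_heads, rng)
        self.generators = [
            _Generator(token_dim, gen_hidden, hidden_width, rng) for _ in range(3)
        ]

    def _tokenize(self, planes: Tensor) -> Tensor:
        H, W, D = self.grid_shape
        ph, pw, pd = self.patch_size
        x = planes.reshape(6, H // ph, ph, W // pw, pw, D // pd, pd)
        x = x.transpose((1, 3, 5, 0, 2, 4, 6))
        n_tokens = (H // ph) * (W // pw) * (D // pd)
        return x.reshape(n_tokens, 6 * ph * pw * pd)

    def __call__(self, x) -> Modulation:
        planes = x.planes if hasattr(x, "planes") else x
        planes = Tensor.as_tensor(planes)
        if planes.ndim != 4 or planes.shape[0] != 6:
            raise ValueError("modulator input must be a 6-plane volume stack")
        if planes.shape[1:] != self.grid_shape:
            raise ValueError("modulator grid mismatch")
        tok = self.embed(self._tokenize(planes))
        tok = tok + self.attn(self.ln1(tok))  # transformer encoder block
        tok = tok + self.mlp2(self.mlp1(self.ln2(tok)).leaky_relu(0.2))
        att = self.token_attn(self.ln3(tok))
        ctx = att.mean(axis=0)  # mean pooling over tokens
        gammas, betas = [], []
        for gen in self.generators:
            g, b = gen(ctx)
            gammas.append(g)
            betas.append(b)
        return Modulation(gammas, betas)


class CNNModulator(Module):
    """Convolutional modulation encoder (the no-attention ablation baseline):
    two strided conv blocks, global average pooling, same generators."""

    def __init__(self, grid_shape, hidden_width: int, channels: int = 8,
                 gen_hidden: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.grid_shape = tuple(int(n) for n in grid_shape)
        self.conv1 = Conv3d(6, channels, 3, rng, stride=2)
        self.conv2 = Conv3d(channels, 2 * channels, 3, rng, stride=2)
        self.generators = [
            _Generator(2 * channels, gen_hidden, hidden_width, rng)
            for _ in range(3)
        ]

    def __call__(self, x) -> Modulation:
        planes = x.planes if hasattr(x, "planes") else x
        planes = Tensor.as_tensor(planes)
        if planes.ndim != 4 or planes.shape[0] != 6:
            raise ValueError("modulator input must be a 6-plane volume stack")
        h = self.conv1(planes).leaky_relu(0.2)
        h = self.conv2(h).leaky_relu(0.2)
        ctx = h.reshape(h.shape[0], -1).mean(axis=1)
        gammas, betas = [], []
        for gen in self.generators:
            g, b = gen(ctx)
            gammas.append(g)
            betas.append(b)
        return Modulation(gammas, betas)
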