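"""Lite population registration network providing deformation priors.

A small UNet-style encoder-decoder (VoxelMorph-like role) maps the
six-plane preprocessed input to a dense 3-component DVF at full
resolution, and exposes its bottleneck features as latent embeddings for
the embedding-similarity loss.  Channel width and depth are deliberately
small so cohort training is feasible on a single CPU; the published-scale
layout is reachable through configuration only.

The network is trained unsupervised across subjects by minimising the
k-space fidelity loss of the deformed source plus a smoothness penalty
(lambda1 = 1.0, lambda3 = 0.5), on randomly drawn bin pairs with random
golden-angle trajectories.  Once trained it is frozen: meta-training and
adaptation only read its predictions and embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, no_grad
from .kspace import ModelInput, nudft_forward_t, nudft_matrix
from .losses import LossWeights, loss_kspace, loss_smooth
from .nn import Adam, Conv3d, Module
from .ops import resize_trilinear, trilinear_sample
from .seeding import rng_for
from .volumes import ComplexVolume, DVF

__all__ = ["PriorNet", "EmbeddingSet", "prior_predict", "prior_encode", "train_prior"]


@dataclass
class EmbeddingSet:
    """N_e latent vectors (one per bottleneck spatial position)."""

    vectors: np.ndarray  # (N_e, C_e)

    def __post_init__(self):
        if not isinstance(self.vectors, Tensor):
            self.vectors = np.asarray(self.vectors, dtype=np.float64)

    @property
    def n_vectors(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


class PriorNet(Module):
    """Encoder-decoder with skip connection; 6 input planes -> 3 DVF planes."""

    def __init__(self, base_channels: int = 8, seed: int = 0):
        rng = np.random.default_rng(seed)
        C = int(base_channels)
        self.base_channels = C
        self.enc1 = Conv3d(6, C, 3, rng)
        self.enc2 = Conv3d(C, C, 3, rng)
        self.down = Conv3d(C, 2 * C, 3, rng, stride=2)
        self.bott = Conv3d(2 * C, 2 * C, 3, rng)
        self.dec1 = Conv3d(3 * C, C, 3, rng)
        # flow head initialised tiny so the untrained net predicts ~zero motion
        self.flow = Conv3d(C, 3, 3, rng, weight_scale=1e-4)
        self.trained = False

    @property
    def bottleneck_channels(self) -> int:
        return 2 * self.base_channels

    # -- differentiable passes ------------------------------------------------
    def encode_t(self, planes6: Tensor) -> Tensor:
        """Six-plane stack -> bottleneck feature map (2C, H', W', D')."""
        h = self.enc1(planes6).leaky_relu(0.2)
        self._skip = self.enc2(h).leaky_relu(0.2)
        h = self.down(self._skip).leaky_relu(0.2)
        return self.bott(h).leaky_relu(0.2)

    def forward_t(self, planes6: Tensor) -> Tensor:
        bott = self.encode_t(planes6)
        up = resize_trilinear(bott, self._skip.shape[1:])
        h = self.dec1(ad.concatenate([up, self._skip], axis=0)).leaky_relu(0.2)
        return self.flow(h)  # (3, H, W, D)


def prior_predict(net: PriorNet, x: ModelInput, spacing_mm=None) -> DVF:
    """Predict a dense reference DVF (voxel units) from the six-plane input."""
    planes = x.planes if isinstance(x, ModelInput) else np.asarray(x)
    if planes.ndim != 4 or planes.shape[0] != 6:
        raise ValueError("prior_predict expects a 6-plane input")
    with no_grad():
        field = net.forward_t(Tensor(planes)).data
    spacing = spacing_mm or getattr(x, "spacing_mm", (1.0, 1.0, 1.0))
    return DVF(field, spacing)


def _tile_planes(planes2: np.ndarray | Tensor):
    """Adapter feeding 2-plane complex volumes to the 6-plane encoder: the
    real/imag pair is tiled three times (the encoder is frozen; no retraining)."""
    if isinstance(planes2, Tensor):
        return ad.concatenate([planes2, planes2, planes2], axis=0)
    return np.concatenate([planes2] * 3, axis=0)


def prior_encode(net: PriorNet, vol: ComplexVolume) -> EmbeddingSet:
    """Bottleneck embeddings of a complex volume, reshaped to N_e vectors."""
    planes6 = _tile_planes(vol.planes())
    with no_grad():
        bott = net.encode_t(Tensor(planes6)).data
    c = bott.shape[0]
    return EmbeddingSet(bott.reshape(c, -1).T.copy())


def encode_tensor(net: PriorNet, planes2: Tensor) -> Tensor:
    """Differentiable embedding pass used inside the step-B loss graph."""
    bott = net.encode_t(_tile_planes(planes2))
    c = bott.shape[0]
    return bott.reshape(c, -1).transpose((1, 0))


def train_prior(
    net: PriorNet,
    cohort,
    epochs: int,
    lr: float = 1e-5,
    n_spokes_range=(5, 13),
    samples_per_spoke: int = 64,
    downsample: int = 2,
    weights: LossWeights | None = None,
    seed: int = 0,
) -> tuple[PriorNet, list[float]]:
    """Unsupervised cohort training on random (source, target) bin pairs.

    One epoch = one gradient step per subject.  Returns the net (modified in
    place) and the per-epoch mean loss history.  ``epochs=0`` is a no-op.
    """
    from .kspace import golden_angle_trajectory, nudft_forward, preprocess_case
    from .losses import loss_stepB

    if not cohort:
        raise ValueError("empty cohort")
    w = weights or LossWeights(1.0, 0.0, 0.5)
    opt = Adam(net.parameters(), lr=lr)
    rng = rng_for(seed, "train-prior")
    history: list[float] = []
    for epoch in range(int(epochs)):
        losses = []
        for subj in cohort:
            bins = rng.choice(subj.n_bins, size=2, replace=False)
            src, tgt = subj.volumes[bins[0]], subj.volumes[bins[1]]
            n_spokes = int(rng.integers(n_spokes_range[0], n_spokes_range[1] + 1))
            traj = golden_angle_trajectory(
                n_spokes, samples_per_spoke,
                seed_for_theta0=int(rng.integers(2**31 - 1)),
            )
            t_uk = nudft_forward(tgt, traj)
            x, _, _, _ = preprocess_case(src, t_uk)
            A = nudft_matrix(traj, src.shape[:2])
            field = net.forward_t(Tensor(x.planes))
            warped = trilinear_sample(Tensor(src.planes()), field)
            yr, yi = nudft_forward_t(warped[0], warped[1], traj, matrix=A)
            lk = loss_kspace((yr, yi), (t_uk.values.real, t_uk.values.imag))
            ls = loss_smooth(field)
            total = loss_stepB(lk, 0.0, ls, w)
            opt.zero_grad()
            total.backward()
            opt.step()
            losses.append(total.item())
        history.append(float(np.mean(losses)))
    if epochs > 0:
        net.trained = True
    return net, history
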