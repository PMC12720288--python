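"""Loss functions for the two-step optimisation scheme.

Step A uses the cohort-informed deformation discrepancy (per-component
mean absolute difference between the INR-predicted and reference DVFs).
Step B combines a complex k-space mean-squared-error fidelity term, an
embedding cosine-similarity term, and a deformation-energy smoothness
term with weights (lambda1, lambda2, lambda3) = (1.0, 0.5, 0.5).

All losses accept either plain numpy arrays (returning a float) or
autodiff tensors (returning a scalar tensor on the graph).  On DVFs the
convention is ``(3, H, W, D)`` fields in voxel units; smoothness uses
forward differences with a replicate boundary (last difference zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

__all__ = [
    "LossWeights",
    "loss_stepA",
    "loss_kspace",
    "loss_embed",
    "loss_smooth",
    "loss_stepB",
]


@dataclass
class LossWeights:
    lambda1: float = 1.0  # k-space fidelity
    lambda2: float = 0.5  # embedding similarity
    lambda3: float = 0.5  # smoothness

    def __post_init__(self):
        for v in (self.lambda1, self.lambda2, self.lambda3):
            if not np.isfinite(v) or v < 0:
                raise ValueError("loss weights must be finite and non-negative")


def _wrap(x):
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x, dtype=np.float64)), False


def _field(x):
    """Accept DVF dataclasses, tensors or raw (3,H,W,D) arrays."""
    if hasattr(x, "field") and not isinstance(x, Tensor):
        x = x.field
    t, was = _wrap(x)
    if t.ndim != 4 or t.shape[0] != 3:
        raise ValueError("expected a (3, H, W, D) displacement field")
    return t, was


def _ret(t: Tensor, any_tensor: bool):
    return t if any_tensor else t.item()


def loss_stepA(d_inr, d_reg):
    """Sum over x,y,z of the mean absolute per-voxel component difference."""
    a, ta = _field(d_inr)
    b, tb = _field(d_reg)
    if a.shape != b.shape:
        raise ValueError(f"DVF shape mismatch: {a.shape} vs {b.shape}")
    diff = (a - b).abs()
    out = diff.mean(axis=(1, 2, 3)).sum()
    return _ret(out, ta or tb)


def loss_kspace(s_dk, t_uk):
    """Mean squared complex modulus of the k-space residual, over all N_k.

    Accepts :class:`~cminr.kspace.KSpaceData` (trajectories must match) or
    (real, imag) tensor pairs from the differentiable forward operator.
    """
    if isinstance(s_dk, tuple):
        pr, pi = s_dk
        tr, ti = t_uk
        pr, w1 = _wrap(pr)
        pi, w2 = _wrap(pi)
        tr, _ = _wrap(tr)
        ti, _ = _wrap(ti)
        if pr.shape != tr.shape:
            raise ValueError("k-space sample shape mismatch")
        dr = pr - tr
        di = pi - ti
        return _ret((dr * dr + di * di).mean(), w1 or w2)
    # KSpaceData path
    if s_dk.trajectory is not t_uk.trajectory and not (
        np.array_equal(
            s_dk.trajectory.sample_coords, t_uk.trajectory.sample_coords
        )
    ):
        raise ValueError("k-space losses require identical trajectories")
    if s_dk.values.shape != t_uk.values.shape:
        raise ValueError("k-space sample count mismatch")
    resid = s_dk.values - t_uk.values
    return float(np.mean(np.abs(resid) ** 2))


def loss_embed(e1, e2, negate: bool = True, eps: float = 1e-12):
    """Mean cosine similarity over embedding-vector pairs.

    ``negate=True`` (default) returns the negated mean so that *minimising*
    the loss increases similarity; the literal printed form (un-negated) is
    available with ``negate=False``.  Zero-norm vectors contribute 0 with a
    warning.
    """
    if hasattr(e1, "vectors") and not isinstance(e1, Tensor):
        e1 = e1.vectors
    if hasattr(e2, "vectors") and not isinstance(e2, Tensor):
        e2 = e2.vectors
    a, ta = _wrap(e1)
    b, tb = _wrap(e2)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("embedding sets must share shape (N_e, dim)")
    na = (a * a).sum(axis=1, keepdims=True)
    nb = (b * b).sum(axis=1, keepdims=True)
    zero = (na.data <= eps) | (nb.data <= eps)
    if np.any(zero):
        warnings.warn("zero-norm embedding vectors contribute 0 to loss_embed")
    dot = (a * b).sum(axis=1, keepdims=True)
    cos = dot / ((na + eps).sqrt() * (nb + eps).sqrt())
    mean_cos = cos.mean()
    out = -mean_cos if negate else mean_cos
    return _ret(out, ta or tb)


def loss_smooth(d):
    """Mean deformation energy: squared forward differences along x, y, z.

    The last voxel along each axis uses a replicated neighbour, i.e. a zero
    difference, so boundaries carry no spurious energy.
    """
    f, tf = _field(d)
    n = f.data[0].size
    total = None
    for axis in range(1, 4):
        n_ax = f.shape[axis]
        sl_hi = [slice(None)] * 4
        sl_lo = [slice(None)] * 4
        sl_hi[axis] = slice(1, n_ax)
        sl_lo[axis] = slice(0, n_ax - 1)
        diff = f[tuple(sl_hi)] - f[tuple(sl_lo)]
        term = (diff * diff).sum() * (1.0 / n)  # mean over all N voxels
        total = term if total is None else total + term
    return _ret(total, tf)


def loss_stepB(k, e, s, weights: LossWeights | None = None):
    """Weighted sum lambda1*k + lambda2*e + lambda3*s."""
    w = weights or LossWeights()
    terms = [k * w.lambda1, e * w.lambda2, s * w.lambda3]
    any_tensor = any(isinstance(t, Tensor) for t in terms)
    out = terms[0] + terms[1] + terms[2]
    if any_tensor and not isinstance(out, Tensor):  # pragma: no cover
        out = Tensor(out)
    return out if any_tensor else float(out)
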