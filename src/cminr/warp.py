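"""DVF resampling and the spatial transformation layer.

Backward (pull) warping with trilinear interpolation and border clamping:
``warped(v) = source(v + d(v))``, applied identically to the real and
imaginary planes of a complex volume.  The displacement field maps
target-grid coordinates into the source volume, which is the convention
the k-space fidelity loss needs (deformed source compared to target).

Numpy-facing functions here wrap the differentiable primitives in
:mod:`cminr.ops`; training code calls those primitives directly on
tensors.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, no_grad
from .ops import resize_trilinear, trilinear_sample
from .volumes import ComplexVolume, DVF

__all__ = ["upsample_dvf", "warp_complex", "warp_mask"]


def upsample_dvf(coarse: DVF, target_shape) -> DVF:
    """Trilinearly resample each displacement component to ``target_shape``.

    Displacement values are already in full-resolution voxel units, so no
    value rescaling is applied — only the grid is refined.
    """
    target_shape = tuple(int(n) for n in target_shape)
    if coarse.grid_shape == target_shape:
        return DVF(coarse.field.copy(), coarse.spacing_mm)
    with no_grad():
        out = resize_trilinear(Tensor(coarse.field), target_shape)
    return DVF(out.data, coarse.spacing_mm)


def warp_complex(vol: ComplexVolume, dvf: DVF) -> ComplexVolume:
    """Warp a complex volume by a DVF (real and imaginary planes alike)."""
    if vol.shape != dvf.grid_shape:
        raise ValueError(f"volume shape {vol.shape} != DVF grid {dvf.grid_shape}")
    with no_grad():
        out = trilinear_sample(Tensor(vol.planes()), Tensor(dvf.field))
    return ComplexVolume(out.data[0], out.data[1], vol.spacing_mm)


def warp_mask(mask: np.ndarray, dvf: DVF) -> np.ndarray:
    """Warp a binary mask with nearest-neighbour interpolation (binarity kept)."""
    mask = np.asarray(mask)
    if mask.shape != dvf.grid_shape:
        raise ValueError("mask/DVF shape mismatch")
    dims = mask.shape
    base = np.meshgrid(*[np.arange(n) for n in dims], indexing="ij")
    idx = [
        np.clip(np.rint(base[a] + dvf.field[a]).astype(int), 0, dims[a] - 1)
        for a in range(3)
    ]
    return mask[tuple(idx)]
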