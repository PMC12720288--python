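"""Differentiable array operators built on :mod:`cminr.autodiff`.

Three linear/sampling primitives that the networks need and that do not
decompose naturally into elementwise ops:

* :func:`unfold3d` — im2col patch extraction (the linear map behind 3D
  convolution); its backward pass is the exact col2im adjoint.
* :func:`resize_trilinear` — separable linear resizing with
  ``align_corners`` semantics (index 0 -> 0, index N-1 -> M-1).
* :func:`trilinear_sample` — backward (pull) warping of a multi-channel
  volume by a dense displacement field, differentiable with respect to
  both the volume values and the displacements; out-of-bounds positions
  are border-clamped (where clamped, displacement gradients vanish).
"""

from __future__ import annotations

import itertools

import numpy as np

from .autodiff import Tensor

__all__ = ["unfold3d", "resize_trilinear", "trilinear_sample"]


def unfold3d(x: Tensor, kernel: int, stride: int = 1, pad: int = 0) -> Tensor:
    """Extract k^3 patches from a (C,H,W,D) tensor -> (L, C*k^3), L=H'*W'*D'."""
    x = Tensor.as_tensor(x)
    C, H, W, D = x.shape
    k, s = kernel, stride
    xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad), (pad, pad)))
    Hp, Wp, Dp = xp.shape[1:]
    Ho, Wo, Do = [(n - k) // s + 1 for n in (Hp, Wp, Dp)]
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
    win = win[:, ::s, ::s, ::s]  # (C, Ho, Wo, Do, k, k, k)
    out_data = np.ascontiguousarray(win.transpose(1, 2, 3, 0, 4, 5, 6)).reshape(
        Ho * Wo * Do, C * k**3
    )

    def backward(g):
        if not x.requires_grad:
            return
        gg = g.reshape(Ho, Wo, Do, C, k, k, k)
        gpad = np.zeros((C, Hp, Wp, Dp))
        for a, b, c in itertools.product(range(k), repeat=3):
            gpad[:, a : a + s * Ho : s, b : b + s * Wo : s, c : c + s * Do : s] += (
                gg[:, :, :, :, a, b, c].transpose(3, 0, 1, 2)
            )
        if pad:
            gpad = gpad[:, pad:-pad, pad:-pad, pad:-pad]
        x._accum(gpad)

    out = Tensor._make(out_data, (x,), backward)
    return out


def _axis_weights(n_old: int, n_new: int):
    """Linear-interpolation gather indices/weights, align-corners convention."""
    if n_new == 1:
        pos = np.zeros(1)
    else:
        pos = np.arange(n_new) * (n_old - 1) / (n_new - 1)
    i0 = np.minimum(np.floor(pos).astype(int), max(n_old - 2, 0))
    f = pos - i0
    return i0, f


def _resize_axis(x: Tensor, n_new: int, axis: int) -> Tensor:
    n_old = x.shape[axis]
    if n_old == n_new:
        return x
    i0, f = _axis_weights(n_old, n_new)
    i1 = np.minimum(i0 + 1, n_old - 1)
    sl0 = [slice(None)] * x.ndim
    shape_f = [1] * x.ndim
    shape_f[axis] = n_new
    fb = f.reshape(shape_f)
    a = np.take(x.data, i0, axis=axis)
    b = np.take(x.data, i1, axis=axis)
    out_data = a * (1 - fb) + b * fb

    def backward(g):
        if not x.requires_grad:
            return
        gg = np.zeros_like(x.data)
        idx0 = [slice(None)] * x.ndim
        ga = g * (1 - fb)
        gb = g * fb
        # scatter-add along `axis`
        for j in range(n_new):
            idx0[axis] = i0[j]
            sl = [slice(None)] * x.ndim
            sl[axis] = j
            gg[tuple(idx0)] += ga[tuple(sl)]
            idx0[axis] = i1[j]
            gg[tuple(idx0)] += gb[tuple(sl)]
        x._accum(gg)

    return Tensor._make(out_data, (x,), backward)


def resize_trilinear(x: Tensor, target_shape) -> Tensor:
    """Resize the three trailing axes of ``x`` to ``target_shape`` linearly.

    Exactly reproduces per-component linear fields and preserves constants;
    used both for DVF upsampling and for decoder upsampling in the prior net.
    """
    x = Tensor.as_tensor(x)
    if len(target_shape) != 3:
        raise ValueError("target_shape must be a length-3 tuple")
    for k, n in enumerate(target_shape):
        x = _resize_axis(x, int(n), x.ndim - 3 + k)
    return x


def trilinear_sample(vol: Tensor, disp: Tensor) -> Tensor:
    """Backward-warp ``vol`` (C,H,W,D) by ``disp`` (3,H,W,D), voxel units.

    ``out[c, v] = vol[c, v + disp[:, v]]`` with trilinear interpolation and
    border clamping.  Differentiable w.r.t. both arguments.
    """
    vol = Tensor.as_tensor(vol)
    disp = Tensor.as_tensor(disp)
    if vol.ndim != 4 or disp.ndim != 4 or disp.shape[0] != 3:
        raise ValueError("vol must be (C,H,W,D) and disp (3,H,W,D)")
    if vol.shape[1:] != disp.shape[1:]:
        raise ValueError(
            f"volume grid {vol.shape[1:]} != displacement grid {disp.shape[1:]}"
        )
    C = vol.shape[0]
    dims = vol.shape[1:]
    base = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in dims], indexing="ij")
    pos_raw = [base[a] + disp.data[a] for a in range(3)]
    # border clamp; keep a mask of where the position was strictly interior so
    # displacement gradients vanish on clamped samples
    interior = [
        (p > 0) & (p < n - 1) for p, n in zip(pos_raw, dims)
    ]
    pos = [np.clip(p, 0, n - 1) for p, n in zip(pos_raw, dims)]
    i0 = [np.minimum(np.floor(p).astype(int), max(n - 2, 0)) for p, n in zip(pos, dims)]
    f = [p - i for p, i in zip(pos, i0)]

    H, W, D = dims
    volf = vol.data.reshape(C, -1)
    nvox = H * W * D

    corners = list(itertools.product((0, 1), repeat=3))
    lin_idx = {}
    wts = {}
    for dx, dy, dz in corners:
        ix = np.minimum(i0[0] + dx, H - 1)
        iy = np.minimum(i0[1] + dy, W - 1)
        iz = np.minimum(i0[2] + dz, D - 1)
        lin_idx[(dx, dy, dz)] = (ix * W + iy) * D + iz
        wts[(dx, dy, dz)] = (
            (f[0] if dx else 1 - f[0])
            * (f[1] if dy else 1 - f[1])
            * (f[2] if dz else 1 - f[2])
        )

    out_data = np.zeros((C,) + dims)
    for key in corners:
        out_data += wts[key][None] * volf[:, lin_idx[key].ravel()].reshape((C,) + dims)

    def backward(g):
        if vol.requires_grad:
            gv = np.zeros((C, nvox))
            for key in corners:
                np.add.at(
                    gv.T, lin_idx[key].ravel(), (g * wts[key][None]).reshape(C, -1).T
                )
            vol._accum(gv.reshape(vol.shape))
        if disp.requires_grad:
            gd = np.zeros((3,) + dims)
            for dx, dy, dz in corners:
                vals = volf[:, lin_idx[(dx, dy, dz)].ravel()].reshape((C,) + dims)
                contrib = (g * vals).sum(axis=0)
                wx = f[0] if dx else 1 - f[0]
                wy = f[1] if dy else 1 - f[1]
                wz = f[2] if dz else 1 - f[2]
                sx = 1.0 if dx else -1.0
                sy = 1.0 if dy else -1.0
                sz = 1.0 if dz else -1.0
                gd[0] += contrib * sx * wy * wz
                gd[1] += contrib * wx * sy * wz
                gd[2] += contrib * wx * wy * sz
            for a in range(3):
                gd[a] *= interior[a]
            disp._accum(gd)

    return Tensor._make(out_data, (vol, disp), backward)
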