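"""Golden-angle radial k-space simulation and preprocessing.

Implements stack-of-stars sampling: a single 2D radial trajectory (spokes
rotated by the golden angle, 111.25 deg) applied identically to every
axial slice of a 3D volume.  The non-uniform transforms are *direct*
discrete sums (type-3 NUDFT) evaluated through a precomputed sample-by-
pixel matrix, which doubles as the differentiable forward operator used by
the k-space fidelity loss.

Conventions (documented once, relied on everywhere):

* k-space coordinates are in radians/voxel, spokes span the full diameter
  with radii ``linspace(-pi, pi, n, endpoint=False)`` (the +pi edge sample
  is excluded by default; include it with ``include_edge=True``);
* the zero-frequency phase reference sits at voxel ``floor(N/2)`` (0-based)
  per in-plane axis, so a centered delta transforms to unit samples;
* the adjoint is normalised by the per-slice sample count, keeping
  reconstruction magnitudes on the image scale across spoke counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .volumes import ComplexVolume

__all__ = [
    "GOLDEN_ANGLE_DEG",
    "RadialTrajectory",
    "KSpaceData",
    "ModelInput",
    "golden_angle_trajectory",
    "nudft_matrix",
    "nudft_forward",
    "nudft_adjoint",
    "nudft_forward_t",
    "acceleration_factor",
    "preprocess_case",
]

GOLDEN_ANGLE_DEG = 111.25  # exact printed value


@dataclass
class RadialTrajectory:
    """2D golden-angle radial readout shared by all slices."""

    n_spokes: int
    samples_per_spoke: int = 256
    theta0_rad: float = 0.0
    include_edge: bool = False
    angles_rad: np.ndarray = field(init=False)
    sample_coords: np.ndarray = field(init=False)  # (n_samples, 2), |k| <= pi

    def __post_init__(self):
        if self.n_spokes < 1:
            raise ValueError("n_spokes must be >= 1")
        if self.samples_per_spoke < 2:
            raise ValueError("samples_per_spoke must be >= 2")
        delta = np.deg2rad(GOLDEN_ANGLE_DEG)
        self.angles_rad = np.mod(
            self.theta0_rad + delta * np.arange(self.n_spokes), 2 * np.pi
        )
        radii = np.linspace(
            -np.pi, np.pi, self.samples_per_spoke, endpoint=self.include_edge
        )
        kx = np.outer(np.cos(self.angles_rad), radii)
        ky = np.outer(np.sin(self.angles_rad), radii)
        self.sample_coords = np.stack([kx.ravel(), ky.ravel()], axis=1)

    @property
    def n_samples(self) -> int:
        """Samples per slice (n_spokes * samples_per_spoke)."""
        return self.n_spokes * self.samples_per_spoke


def golden_angle_trajectory(
    n_spokes: int,
    samples_per_spoke: int = 256,
    theta0_rad: float = 0.0,
    seed_for_theta0: int | None = None,
    include_edge: bool = False,
) -> RadialTrajectory:
    """Build a golden-angle trajectory; optionally draw theta0 ~ U[0, 2pi)."""
    if seed_for_theta0 is not None:
        theta0_rad = float(
            np.random.default_rng(seed_for_theta0).uniform(0, 2 * np.pi)
        )
    return RadialTrajectory(n_spokes, samples_per_spoke, theta0_rad, include_edge)


@dataclass
class KSpaceData:
    """Non-Cartesian samples for every slice of a volume.

    ``values`` has shape ``(n_samples, D)``: per-slice sample vectors for the
    shared in-plane trajectory.  Total sample count N_k = n_samples * D.
    """

    values: np.ndarray
    trajectory: RadialTrajectory

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 2:
            raise ValueError("values must be (n_samples, n_slices)")
        if self.values.shape[0] != self.trajectory.n_samples:
            raise ValueError("sample count does not match trajectory")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("k-space values must be finite")

    @property
    def slice_count(self) -> int:
        return self.values.shape[1]

    @property
    def n_k(self) -> int:
        return self.values.size


@dataclass
class ModelInput:
    """Six-plane real stack X = (Re/Im S_FI, Re/Im S_UI, Re/Im T_UI)."""

    planes: np.ndarray  # (6, H, W, D)
    spacing_mm: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.planes = np.asarray(self.planes, dtype=np.float64)
        if self.planes.ndim != 4 or self.planes.shape[0] != 6:
            raise ValueError("ModelInput requires exactly 6 planes")

    @property
    def grid_shape(self):
        return self.planes.shape[1:]


def nudft_matrix(traj: RadialTrajectory, shape2d) -> np.ndarray:
    """(n_samples, H*W) matrix A with A[s,p] = exp(-i(kx*(m-cx)+ky*(n-cy)))."""
    H, W = shape2d
    cx, cy = H // 2, W // 2
    m = np.arange(H) - cx
    n = np.arange(W) - cy
    phase = (
        traj.sample_coords[:, 0, None, None] * m[None, :, None]
        + traj.sample_coords[:, 1, None, None] * n[None, None, :]
    ).reshape(traj.n_samples, H * W)
    return np.exp(-1j * phase)


def nudft_forward(
    vol: ComplexVolume, traj: RadialTrajectory, matrix: np.ndarray | None = None
) -> KSpaceData:
    """Slice-wise direct NUDFT of a complex volume."""
    H, W, D = vol.shape
    A = nudft_matrix(traj, (H, W)) if matrix is None else matrix
    x = vol.data.reshape(H * W, D)
    return KSpaceData(A @ x, traj)


def nudft_adjoint(
    k: KSpaceData, shape, matrix: np.ndarray | None = None,
    spacing_mm=(1.0, 1.0, 1.0),
) -> ComplexVolume:
    """Adjoint (conjugate-transposed sum) divided by the per-slice N_k."""
    H, W, D = shape
    if k.slice_count != D:
        raise ValueError("slice count mismatch")
    A = nudft_matrix(k.trajectory, (H, W)) if matrix is None else matrix
    x = (A.conj().T @ k.values) / k.trajectory.n_samples
    return ComplexVolume.from_complex(x.reshape(H, W, D), spacing_mm)


def nudft_forward_t(
    real: Tensor, imag: Tensor, traj: RadialTrajectory,
    matrix: np.ndarray | None = None,
) -> tuple[Tensor, Tensor]:
    """Differentiable NUDFT on (H,W,D) real/imag tensors -> (n_samples, D)."""
    H, W, D = real.shape
    A = nudft_matrix(traj, (H, W)) if matrix is None else matrix
    C = Tensor(A.real)
    S = Tensor(A.imag)
    xr = real.reshape(H * W, D)
    xi = imag.reshape(H * W, D)
    yr = C @ xr - S @ xi
    yi = C @ xi + S @ xr
    return yr, yi


def acceleration_factor(matrix_size: int, n_spokes: int) -> float:
    """(pi/2 * matrix_size) / n_spokes: radial-Nyquist spokes over acquired."""
    if matrix_size < 1 or n_spokes < 1:
        raise ValueError("matrix_size and n_spokes must be >= 1")
    return (np.pi / 2 * matrix_size) / n_spokes


def acceleration_factor_rounded(matrix_size: int, n_spokes: int) -> int:
    return int(round(acceleration_factor(matrix_size, n_spokes)))


def preprocess_case(
    s_fi: ComplexVolume, t_uk: KSpaceData
) -> tuple[ModelInput, ComplexVolume, ComplexVolume, KSpaceData]:
    """Figure-style input preprocessing: (S_FI, T_UK) -> (X, S_UI, T_UI, S_UK).

    The source is projected into k-space with the *target's* trajectory so the
    undersampled source image S_UI carries the same streak artifacts as T_UI.
    """
    H, W, D = s_fi.shape
    if t_uk.slice_count != D:
        raise ValueError("target k-space slice count does not match source grid")
    A = nudft_matrix(t_uk.trajectory, (H, W))
    s_uk = nudft_forward(s_fi, t_uk.trajectory, matrix=A)
    s_ui = nudft_adjoint(s_uk, s_fi.shape, matrix=A, spacing_mm=s_fi.spacing_mm)
    t_ui = nudft_adjoint(t_uk, s_fi.shape, matrix=A, spacing_mm=s_fi.spacing_mm)
    planes = np.concatenate([s_fi.planes(), s_ui.planes(), t_ui.planes()])
    return ModelInput(planes, s_fi.spacing_mm), s_ui, t_ui, s_uk
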