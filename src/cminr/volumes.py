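"""Core data containers: complex image volumes and deformation fields."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ComplexVolume", "DVF"]


@dataclass
class ComplexVolume:
    """A 3D complex-valued MR image on a voxel grid.

    Stored as separate real/imaginary planes (shape ``(H, W, D)``) with voxel
    spacing in millimetres.  The grid axes are (x, y, z) = (array axes
    0, 1, 2); the third axis is the slice/through-plane direction.
    """

    real: np.ndarray
    imag: np.ndarray
    spacing_mm: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.real = np.asarray(self.real, dtype=np.float64)
        self.imag = np.asarray(self.imag, dtype=np.float64)
        if self.real.shape != self.imag.shape:
            raise ValueError("real/imag shape mismatch")
        if self.real.ndim != 3:
            raise ValueError("volumes must be 3-D")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")

    @classmethod
    def from_complex(cls, data: np.ndarray, spacing_mm=(1.0, 1.0, 1.0)):
        data = np.asarray(data)
        return cls(data.real.copy(), data.imag.copy(), spacing_mm)

    @classmethod
    def from_magnitude_phase(cls, magnitude, phase, spacing_mm=(1.0, 1.0, 1.0)):
        """Standard phase-augmentation construction: m * exp(i*phi)."""
        magnitude = np.asarray(magnitude, dtype=np.float64)
        phase = np.asarray(phase, dtype=np.float64)
        return cls(magnitude * np.cos(phase), magnitude * np.sin(phase), spacing_mm)

    @property
    def data(self) -> np.ndarray:
        return self.real + 1j * self.imag

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.real, self.imag)

    @property
    def shape(self) -> tuple:
        return self.real.shape

    def planes(self) -> np.ndarray:
        """(2, H, W, D) stack of the real and imaginary planes."""
        return np.stack([self.real, self.imag])


@dataclass
class DVF:
    """Dense 3-component displacement field in full-resolution voxel units.

    ``field`` has shape ``(3, H, W, D)``; component ``j`` displaces along grid
    axis ``j`` (component order x, y, z).  The field follows the backward-warp
    convention: it maps target-grid coordinates into the source volume, i.e.
    ``warped(v) = source(v + d(v))``.
    """

    field: np.ndarray
    spacing_mm: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.field = np.asarray(self.field, dtype=np.float64)
        if self.field.ndim != 4 or self.field.shape[0] != 3:
            raise ValueError("DVF field must have shape (3, H, W, D)")
        if not np.all(np.isfinite(self.field)):
            raise ValueError("DVF contains non-finite values")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @classmethod
    def zeros(cls, shape, spacing_mm=(1.0, 1.0, 1.0)):
        return cls(np.zeros((3,) + tuple(shape)), spacing_mm)

    @property
    def grid_shape(self) -> tuple:
        return self.field.shape[1:]

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))

    def magnitude(self) -> np.ndarray:
        return np.sqrt((self.field**2).sum(axis=0))

    def approx_inverse(self) -> "DVF":
        """Small-displacement inverse approximation (negated field)."""
        return DVF(-self.field, self.spacing_mm)
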