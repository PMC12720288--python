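"""Synthetic cohorts of complex-valued, motion-resolved 3D phantoms.

The generator emulates the data-synthesis recipe used for magnitude-only
4D-MRI: ellipsoid phantoms stand in for anatomy, complex volumes are built
as ``magnitude * exp(i * phase)`` with smooth sinusoidal phase maps (four
spatial frequencies per Cartesian axis by default), respiratory-like
smooth motion deforms both magnitude and phase with the *same* field, and
independent Gaussian noise is added to the real and imaginary planes.

Unlike clinical data, ground-truth deformation fields are known exactly
here (the motion is analytic), which is what parameter-recovery tests
require.  Bin 0 is always the reference (source) bin with zero motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .seeding import child_seed, rng_for
from .volumes import ComplexVolume, DVF
from .warp import warp_complex, warp_mask

__all__ = [
    "Ellipsoid",
    "PhantomSpec",
    "MotionModel",
    "PhaseMapSpec",
    "NoiseSpec",
    "Subject",
    "generate_phantom",
    "make_phase_map",
    "analytic_motion_dvf",
    "add_complex_noise",
    "generate_cohort",
]


@dataclass
class Ellipsoid:
    center: tuple  # voxel coordinates
    semi_axes: tuple  # voxels, all > 0
    intensity: float  # in [0, 1]

    def __post_init__(self):
        self.center = tuple(float(c) for c in self.center)
        self.semi_axes = tuple(float(s) for s in self.semi_axes)
        if any(s <= 0 for s in self.semi_axes):
            raise ValueError("semi-axes must be positive")
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError("intensity must lie in [0, 1]")


@dataclass
class PhantomSpec:
    grid_shape: tuple = (32, 32, 8)
    spacing_mm: tuple = (4.0, 4.0, 8.0)
    structures: list = field(default_factory=list)
    background_intensity: float = 0.05
    texture_amp: float = 0.0  # smooth random texture amplitude (0 = uniform)
    texture_scale_vox: float = 3.0
    edge_smooth_vox: float = 0.0  # Gaussian smoothing of structure edges

    def __post_init__(self):
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if any(a < b for a, b in zip(self.grid_shape, (8, 8, 4))):
            raise ValueError("grid_shape must be at least (8, 8, 4)")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        if not 0.0 <= self.background_intensity < 1.0:
            raise ValueError("background intensity must lie in [0, 1)")
        self.structures = [
            s if isinstance(s, Ellipsoid) else Ellipsoid(**s) for s in self.structures
        ]


@dataclass
class MotionModel:
    """Respiratory-like analytic motion surrogate.

    A separable Gaussian spatial envelope times a sinusoidal bin factor:
    ``d_j(v, t) = amplitude_vox[j] * sin(pi * t) * exp(-|v - c|^2 / 2s^2)``.
    Peak displacement per axis is bounded by ``amplitude_vox``; the field is
    C^1-smooth by construction.  Defaults put the dominant motion along the
    slice axis, mimicking cranio-caudal respiration.
    """

    amplitude_vox: tuple = (0.5, 1.0, 2.0)
    spatial_scale: float = 8.0
    n_bins: int = 4

    def __post_init__(self):
        self.amplitude_vox = tuple(float(a) for a in self.amplitude_vox)
        if self.spatial_scale <= 0:
            raise ValueError("spatial_scale must be positive")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")


@dataclass
class PhaseMapSpec:
    """3D sinusoidal phase maps: ``n_freqs_per_axis`` components per axis with
    frequencies drawn uniformly from ``freq_range_per_mm`` (defaults span
    wavelengths 800 mm down to 400 mm) and independent uniform phase shifts."""

    n_freqs_per_axis: int = 4
    freq_range_per_mm: tuple = (1.25e-3, 2.50e-3)
    amplitude: float = 1.0
    random_shifts: bool = True  # False: zero phase shifts (analytic checks)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.freq_range_per_mm
        if not (0 < lo <= hi):
            raise ValueError("freq_range bounds must be positive and ordered")
        if self.n_freqs_per_axis < 1:
            raise ValueError("n_freqs_per_axis must be >= 1")


@dataclass
class NoiseSpec:
    """Zero-mean Gaussian noise on real and imaginary planes; one standard
    deviation drawn uniformly from ``sd_range`` per call."""

    sd_range: tuple = (3.0e-3, 5.0e-3)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.sd_range
        if not (0 <= lo <= hi):
            raise ValueError("sd_range bounds must be non-negative and ordered")


def generate_phantom(spec: PhantomSpec, seed: int = 0):
    """Render a magnitude phantom and one binary mask per structure.

    Returns ``(magnitude, masks)`` with magnitude in [0, 1].  A structure
    whose bounding box extends outside the grid is rejected.
    """
    shape = spec.grid_shape
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    vol = np.full(shape, spec.background_intensity)
    masks = []
    for ell in spec.structures:
        for c, s, n in zip(ell.center, ell.semi_axes, shape):
            if c - s < 0 or c + s > n - 1:
                raise ValueError(
                    f"structure at {ell.center} with semi-axes {ell.semi_axes} "
                    f"extends outside grid {shape}"
                )
        q = sum(
            ((g - c) / s) ** 2 for g, c, s in zip(grids, ell.center, ell.semi_axes)
        )
        mask = q <= 1.0
        vol[mask] = ell.intensity
        masks.append(mask)
    if spec.edge_smooth_vox > 0:
        vol = gaussian_filter(vol, spec.edge_smooth_vox)
    if spec.texture_amp > 0:
        rng = np.random.default_rng(seed)
        tex = gaussian_filter(rng.standard_normal(shape), spec.texture_scale_vox)
        sd = tex.std()
        if sd > 0:
            vol = vol + spec.texture_amp * tex / sd
    return np.clip(vol, 0.0, 1.0), masks


def make_phase_map(shape, spacing_mm, spec: PhaseMapSpec) -> np.ndarray:
    """Sum of per-axis sinusoids in physical (mm) coordinates, in radians."""
    shape = tuple(int(n) for n in shape)
    if any(s <= 0 for s in spacing_mm):
        raise ValueError("spacing must be positive")
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.freq_range_per_mm
    phase = np.zeros(shape)
    for axis in range(3):
        coord_mm = np.arange(shape[axis]) * spacing_mm[axis]
        freqs = rng.uniform(lo, hi, size=spec.n_freqs_per_axis)
        if spec.random_shifts:
            shifts = rng.uniform(0, 2 * np.pi, size=spec.n_freqs_per_axis)
        else:
            shifts = np.zeros(spec.n_freqs_per_axis)
        axis_sum = np.zeros(shape[axis])
        for f, s in zip(freqs, shifts):
            axis_sum += spec.amplitude * np.sin(2 * np.pi * f * coord_mm + s)
        bshape = [1, 1, 1]
        bshape[axis] = shape[axis]
        phase = phase + axis_sum.reshape(bshape)
    return phase


def analytic_motion_dvf(
    shape, model: MotionModel, bin_fraction: float, spacing_mm=(1.0, 1.0, 1.0)
) -> DVF:
    """Smooth analytic motion field for a given respiratory bin fraction."""
    if not 0.0 <= bin_fraction <= 1.0:
        raise ValueError("bin_fraction must lie in [0, 1]")
    shape = tuple(int(n) for n in shape)
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    centers = [(n - 1) / 2.0 for n in shape]
    r2 = sum((g - c) ** 2 for g, c in zip(grids, centers))
    envelope = np.exp(-0.5 * r2 / model.spatial_scale**2)
    tfac = np.sin(np.pi * bin_fraction)
    field = np.stack([a * tfac * envelope for a in model.amplitude_vox])
    return DVF(field, spacing_mm)


def add_complex_noise(vol: ComplexVolume, spec: NoiseSpec) -> ComplexVolume:
    """Add independent Gaussian noise (one drawn sd) to both planes."""
    rng = np.random.default_rng(spec.seed)
    sd = rng.uniform(*spec.sd_range)
    real = vol.real + rng.normal(0.0, 1.0, vol.shape) * sd
    imag = vol.imag + rng.normal(0.0, 1.0, vol.shape) * sd
    return ComplexVolume(real, imag, vol.spacing_mm)


@dataclass
class Subject:
    """One synthetic subject: motion-resolved complex bins with ground truth."""

    index: int
    spacing_mm: tuple
    magnitude0: np.ndarray  # bin-0 magnitude
    masks0: dict  # name -> bin-0 binary mask
    phase_maps: list  # generated phase maps (first one is applied)
    volumes: list  # ComplexVolume per bin (noisy)
    clean_volumes: list  # ComplexVolume per bin (pre-noise)
    dvfs: list  # DVF per bin; dvfs[0] is identically zero
    bin_masks: list  # per bin: name -> warped mask

    @property
    def n_bins(self) -> int:
        return len(self.volumes)


def _jitter_spec(spec: PhantomSpec, rng: np.random.Generator) -> PhantomSpec:
    """Per-subject anatomical variation: jitter structure centers and axes."""
    structures = []
    for ell in spec.structures:
        for _ in range(20):  # retry until the jittered structure stays in-grid
            center = tuple(
                c + rng.uniform(-1.5, 1.5) for c in ell.center
            )
            semi = tuple(s * rng.uniform(0.85, 1.15) for s in ell.semi_axes)
            ok = all(
                0 <= c - s and c + s <= n - 1
                for c, s, n in zip(center, semi, spec.grid_shape)
            )
            if ok:
                structures.append(Ellipsoid(center, semi, ell.intensity))
                break
        else:
            structures.append(ell)
    return PhantomSpec(
        spec.grid_shape,
        spec.spacing_mm,
        structures,
        spec.background_intensity,
        spec.texture_amp,
        spec.texture_scale_vox,
        spec.edge_smooth_vox,
    )


def generate_cohort(
    n_subjects: int,
    phantom_spec: PhantomSpec,
    motion_model: MotionModel,
    phase_spec: PhaseMapSpec,
    noise_spec: NoiseSpec,
    seed: int = 0,
    n_phase_maps: int = 1,
    jitter_anatomy: bool = True,
) -> list[Subject]:
    """Generate a cohort of subjects with known inter-bin deformations.

    Bin 0 is the reference; bin b carries motion with bin fraction
    ``b / n_bins`` so displacement grows from zero through the cycle.  Phase
    maps are warped with the same DVFs as the magnitude.  ``n_phase_maps``
    mirrors the phase-augmentation count (the first map is applied; all are
    returned on the subject).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    subjects = []
    shape = phantom_spec.grid_shape
    spacing = phantom_spec.spacing_mm
    for si in range(n_subjects):
        srng = rng_for(seed, f"subject-{si}")
        spec_s = _jitter_spec(phantom_spec, srng) if jitter_anatomy else phantom_spec
        mag0, mask_list = generate_phantom(spec_s, child_seed(seed, f"phantom-{si}"))
        masks0 = {f"structure_{j}": m for j, m in enumerate(mask_list)}
        phase_maps = [
            make_phase_map(
                shape,
                spacing,
                PhaseMapSpec(
                    phase_spec.n_freqs_per_axis,
                    phase_spec.freq_range_per_mm,
                    phase_spec.amplitude,
                    child_seed(seed, f"phase-{si}-{pm}"),
                ),
            )
            for pm in range(max(1, n_phase_maps))
        ]
        vol0 = ComplexVolume.from_magnitude_phase(mag0, phase_maps[0], spacing)
        volumes, clean_volumes, dvfs, bin_masks = [], [], [], []
        for b in range(motion_model.n_bins):
            frac = b / motion_model.n_bins
            dvf = analytic_motion_dvf(shape, motion_model, frac, spacing)
            clean = warp_complex(vol0, dvf) if b else vol0
            noisy = add_complex_noise(
                clean,
                NoiseSpec(noise_spec.sd_range, child_seed(seed, f"noise-{si}-{b}")),
            )
            volumes.append(noisy)
            clean_volumes.append(clean)
            dvfs.append(dvf)
            bin_masks.append(
                {k: (warp_mask(m, dvf) if b else m.copy()) for k, m in masks0.items()}
            )
        subjects.append(
            Subject(si, spacing, mag0, masks0, phase_maps, volumes,
                    clean_volumes, dvfs, bin_masks)
        )
    return subjects


def default_phantom_spec(grid_shape=(32, 32, 8), spacing_mm=(4.0, 4.0, 8.0),
                         textured: bool = True) -> PhantomSpec:
    """A liver-like two-structure scene scaled to the requested grid."""
    H, W, D = grid_shape
    structures = [
        Ellipsoid((H * 0.45, W * 0.5, (D - 1) * 0.5),
                  (H * 0.28, W * 0.33, max(D * 0.3, 1.2)), 0.8),
        Ellipsoid((H * 0.55, W * 0.42, (D - 1) * 0.45),
                  (H * 0.10, W * 0.10, max(D * 0.16, 1.0)), 0.35),
    ]
    return PhantomSpec(
        grid_shape,
        spacing_mm,
        structures,
        background_intensity=0.08,
        texture_amp=0.06 if textured else 0.0,
        texture_scale_vox=max(min(H, W) / 10.0, 1.5),
    )
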