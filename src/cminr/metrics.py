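"""Registration evaluation metrics.

Image-quality metrics (global single-window SSIM and relative error) are
computed on magnitude images expected on a [0, 1] intensity scale;
contour metrics (Dice, 95th-percentile Hausdorff distance over boundary
voxels, centre-of-mass error) operate on binary masks with physical
spacing in mm.  Percentiles use numpy's linear-interpolation convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.ndimage import binary_erosion, center_of_mass, generate_binary_structure
from scipy.spatial import cKDTree

__all__ = [
    "MetricReport",
    "ssim",
    "relative_error",
    "dice",
    "hd95",
    "come",
    "evaluate_case",
]

SSIM_C1 = 0.01**2  # stabilisers for a [0, 1] dynamic range
SSIM_C2 = 0.03**2


@dataclass
class MetricReport:
    ssim: float
    re_percent: float
    dice: float | None = None
    hd95_mm: float | None = None
    come_mm: float | None = None
    c1: float = SSIM_C1
    c2: float = SSIM_C2

    def as_dict(self) -> dict:
        return asdict(self)


def ssim(pred: np.ndarray, truth: np.ndarray) -> float:
    """Global (single-window) structural similarity on the whole volume."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError("shape mismatch")
    mu_p, mu_t = pred.mean(), truth.mean()
    var_p, var_t = pred.var(), truth.var()
    cov = ((pred - mu_p) * (truth - mu_t)).mean()
    num = (2 * mu_p * mu_t + SSIM_C1) * (2 * cov + SSIM_C2)
    den = (mu_p**2 + mu_t**2 + SSIM_C1) * (var_p + var_t + SSIM_C2)
    return float(num / den)


def relative_error(pred: np.ndarray, truth: np.ndarray) -> float:
    """sqrt(sum (pred-truth)^2 / sum truth^2) * 100, on magnitude images."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError("shape mismatch")
    denom = np.sum(truth**2)
    if denom == 0:
        raise ValueError("reference volume is identically zero")
    return float(np.sqrt(np.sum((pred - truth) ** 2) / denom) * 100.0)


def _check_masks(m1, m2, need_nonempty=False):
    m1 = np.asarray(m1).astype(bool)
    m2 = np.asarray(m2).astype(bool)
    if m1.shape != m2.shape:
        raise ValueError("mask grid mismatch")
    if need_nonempty and (not m1.any() or not m2.any()):
        raise ValueError("distance metrics require non-empty masks")
    return m1, m2


def dice(m1: np.ndarray, m2: np.ndarray) -> float:
    """2|A∩B| / (|A|+|B|); both empty -> 1 (with a warning)."""
    m1, m2 = _check_masks(m1, m2)
    s = m1.sum() + m2.sum()
    if s == 0:
        warnings.warn("Dice of two empty masks defined as 1")
        return 1.0
    return float(2.0 * np.logical_and(m1, m2).sum() / s)


def _boundary_points(mask: np.ndarray, spacing) -> np.ndarray:
    """Boundary voxels (6-connectivity erosion difference) in mm coordinates."""
    struct = generate_binary_structure(3, 1)
    interior = binary_erosion(mask, structure=struct, border_value=0)
    boundary = mask & ~interior
    pts = np.argwhere(boundary).astype(np.float64)
    return pts * np.asarray(spacing, dtype=np.float64)


def hd95(m1: np.ndarray, m2: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float:
    """95th-percentile symmetric boundary distance in mm."""
    m1, m2 = _check_masks(m1, m2, need_nonempty=True)
    p1 = _boundary_points(m1, spacing)
    p2 = _boundary_points(m2, spacing)
    d12, _ = cKDTree(p2).query(p1)
    d21, _ = cKDTree(p1).query(p2)
    return float(max(np.percentile(d12, 95), np.percentile(d21, 95)))


def come(m1: np.ndarray, m2: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float:
    """Euclidean distance between mask centroids in physical (mm) space."""
    m1, m2 = _check_masks(m1, m2, need_nonempty=True)
    c1 = np.asarray(center_of_mass(m1)) * np.asarray(spacing)
    c2 = np.asarray(center_of_mass(m2)) * np.asarray(spacing)
    return float(np.linalg.norm(c1 - c2))


def evaluate_case(
    pred_magnitude: np.ndarray,
    truth_magnitude: np.ndarray,
    pred_mask: np.ndarray | None = None,
    truth_mask: np.ndarray | None = None,
    spacing=(1.0, 1.0, 1.0),
) -> MetricReport:
    """Full metric report for one registration case."""
    report = MetricReport(
        ssim=ssim(pred_magnitude, truth_magnitude),
        re_percent=relative_error(pred_magnitude, truth_magnitude),
    )
    if pred_mask is not None and truth_mask is not None:
        report.dice = dice(pred_mask, truth_mask)
        if np.asarray(pred_mask).any() and np.asarray(truth_mask).any():
            report.hd95_mm = hd95(pred_mask, truth_mask, spacing)
            report.come_mm = come(pred_mask, truth_mask, spacing)
    return report
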