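"""Accuracy metrics for reconstructed metabolite maps.

Global structural similarity with the stability constants set to zero (valid
because metabolite values inside brain are bounded away from zero), Welch's
unequal-variance t-test, the classical pooled-SD Cohen's d effect size,
median/interquartile ROI summaries, the cylinder-phantom concentration
ratio, and the "white matter surrounding lesions" (NWM) mask used as the
contrast reference region in the lesion analyses.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage, stats

from .grids import LesionMask, TissueProbMaps, VolumeGrid

__all__ = [
    "RoiSummary",
    "ssim_global",
    "welch_t",
    "cohens_d",
    "nwm_mask",
    "roi_summary",
    "cylinder_ratio",
]


@dataclasses.dataclass
class RoiSummary:
    """Median and quartiles over a region of interest."""

    median: float
    q1: float
    q3: float
    n_voxels: int

    def __post_init__(self) -> None:
        if not (self.q1 <= self.median <= self.q3):
            raise ValueError("quartiles must satisfy q1 <= median <= q3")
        if self.n_voxels < 1:
            raise ValueError("ROI must contain at least one voxel")


def _values(volume, mask=None) -> np.ndarray:
    data = volume.data if isinstance(volume, VolumeGrid) else np.asarray(volume)
    data = np.asarray(data, dtype=float)
    if mask is None:
        return data.ravel()
    mask = mask.data if isinstance(mask, LesionMask) else np.asarray(mask)
    return data[mask.astype(bool)]


def ssim_global(x, y, mask=None) -> float:
    """Structural similarity computed once globally over the mask.

    SSIM = (2 mu_x mu_y)(2 sigma_xy) / ((mu_x^2 + mu_y^2)(sigma_x^2 + sigma_y^2))
    with both stability constants zero; means/variances (sample, n-1) are
    taken over the whole masked region rather than sliding windows.
    """
    a = _values(x, mask)
    b = _values(y, mask)
    if a.size != b.size:
        raise ValueError("images must share a grid and mask")
    if a.size < 2:
        raise ValueError("mask must contain at least two voxels")
    mu_a, mu_b = a.mean(), b.mean()
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    cov = float(np.dot(a - mu_a, b - mu_b)) / (a.size - 1)
    denom = (mu_a**2 + mu_b**2) * (va + vb)
    if abs(denom) < 1e-300:
        raise ValueError(
            "zero SSIM denominator (constant images with zero mean); "
            "use non-zero stability constants for such data"
        )
    return float((2.0 * mu_a * mu_b) * (2.0 * cov) / denom)


def _check_sample(s: np.ndarray, name: str) -> np.ndarray:
    s = np.asarray(s, dtype=float).ravel()
    if s.size < 2:
        raise ValueError(f"sample {name} needs n >= 2")
    if s.var(ddof=1) == 0.0:
        raise ValueError(f"sample {name} has zero variance")
    return s


def welch_t(a, b) -> tuple[float, float]:
    """Welch's unequal-variance t statistic and two-sided p-value
    (Welch-Satterthwaite degrees of freedom)."""
    a = _check_sample(a, "a")
    b = _check_sample(b, "b")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def cohens_d(a, b) -> float:
    """Classical Cohen's d: (mean_a - mean_b) / pooled SD (n-1 weighting)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    pooled_var = (
        (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
    ) / (a.size + b.size - 2)
    if pooled_var <= 0.0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def nwm_mask(
    lesions: LesionMask,
    probs: TissueProbMaps,
    radius_voxels: int = 2,
    connectivity: int = 26,
) -> np.ndarray:
    """White matter surrounding lesions.

    Dilates the lesion mask by ``radius_voxels`` (26- or 6-connectivity per
    dilation step), removes the lesions themselves, and keeps only
    WM-dominant voxels (p_WM > 0.5).  Disjoint from the lesion mask by
    construction.
    """
    if radius_voxels < 1:
        raise ValueError("radius must be >= 1")
    if connectivity not in (6, 26):
        raise ValueError("connectivity must be 6 or 26")
    if lesions.shape != probs.shape:
        raise ValueError("lesion mask and probability maps must share a grid")
    structure = ndimage.generate_binary_structure(3, 3 if connectivity == 26 else 1)
    dilated = ndimage.binary_dilation(
        lesions.data, structure=structure, iterations=radius_voxels
    )
    return dilated & ~lesions.data & (probs.class_map("WM") > 0.5)


def roi_summary(volume, mask) -> RoiSummary:
    """Median (q1, q3) summary over the masked voxels, using the linear
    interpolation quantile rule."""
    vals = _values(volume, mask)
    if vals.size == 0:
        raise ValueError("empty ROI")
    q1, med, q3 = np.percentile(vals, [25.0, 50.0, 75.0])
    return RoiSummary(float(med), float(q1), float(q3), int(vals.size))


def cylinder_ratio(volume, labels, num: int, den: int) -> float:
    """Ratio of median values between two labelled compartments."""
    data = volume.data if isinstance(volume, VolumeGrid) else np.asarray(volume)
    lab = labels.data if isinstance(labels, VolumeGrid) else np.asarray(labels)
    num_vals = np.asarray(data, dtype=float)[lab == num]
    den_vals = np.asarray(data, dtype=float)[lab == den]
    if num_vals.size == 0 or den_vals.size == 0:
        raise ValueError("both labels must select at least one voxel")
    return float(np.median(num_vals) / np.median(den_vals))
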