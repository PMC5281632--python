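"""Desk-scale synthetic experiments: phantoms and an acquisition simulator.

Two ground-truth objects are generated procedurally (no downloads):

* a cylindrical acetate phantom -- seven 40 mm cylinders on a ring inside a
  180 mm water cylinder; the first cylinder is empty, the second holds 6 mM
  acetate and each subsequent one 2 mM more, up to 16 mM;
* a brain-like phantom -- concentric ellipsoidal GM/WM/CSF shells with soft
  boundaries, randomly seeded white-matter lesion blobs, an NAA concentration
  map (GM 30, WM 25, lesions 20 arbitrary units) and T1-like / FLAIR-like
  intensity volumes (lesions FLAIR-hyperintense).

The acquisition simulator degrades a high-resolution map the way a
low-resolution phase-encoded acquisition would: additive white Gaussian
noise, an edge-preserving zero-phase anti-alias low-pass per axis (an
odd-length symmetric FIR designed by Chebyshev/equiripple approximation,
cutoff at the target Nyquist frequency), and decimation to the coarse grid
(sampling the filtered signal at each block center, with linear
interpolation when the center falls between samples -- for even factors).
All randomness is driven by the config seed; identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import ndimage, signal

from .grids import LesionMask, TissueProbMaps, VolumeGrid

__all__ = [
    "CylinderPhantomConfig",
    "BrainPhantomConfig",
    "AcquisitionConfig",
    "CylinderPhantom",
    "BrainPhantom",
    "make_cylinder_phantom",
    "make_brain_phantom",
    "simulate_acquisition",
    "antialias_taps",
    "labels_to_probabilities",
]

LESION_LOAD_PRESETS = {"mild": 3, "moderate": 8, "severe": 15}


# ---------------------------------------------------------------------------
# Configurations
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CylinderPhantomConfig:
    """Geometry and contents of the multi-cylinder acetate phantom.

    Cylinder 1 is empty (concentration 0); cylinder i >= 2 holds
    ``base_concentration_mM + (i - 2) * step_mM``.
    """

    outer_diameter_mm: float = 180.0
    cylinder_diameter_mm: float = 40.0
    n_cylinders: int = 7
    base_concentration_mM: float = 6.0
    step_mM: float = 2.0
    hr_spacing_mm: float = 5.0
    slice_thickness_mm: float = 5.0
    n_slices: int = 6
    ring_radius_mm: float = 60.0
    fov_margin_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.n_cylinders < 2:
            raise ValueError("need at least 2 cylinders")
        if self.base_concentration_mM < 0 or self.step_mM < 0:
            raise ValueError("concentrations must be non-negative")
        r = self.cylinder_diameter_mm / 2.0
        chord = 2.0 * self.ring_radius_mm * math.sin(math.pi / self.n_cylinders)
        if chord <= self.cylinder_diameter_mm:
            raise ValueError("cylinders on the ring overlap")
        if self.ring_radius_mm + r >= self.outer_diameter_mm / 2.0:
            raise ValueError("cylinders do not fit inside the outer cylinder")

    @property
    def concentrations(self) -> np.ndarray:
        """Per-cylinder concentration in mM (index 0 = water background)."""
        c = [0.0, 0.0]  # background, empty cylinder 1
        for i in range(2, self.n_cylinders + 1):
            c.append(self.base_concentration_mM + (i - 2) * self.step_mM)
        return np.asarray(c)


@dataclasses.dataclass
class BrainPhantomConfig:
    """Procedural brain-like phantom with GM/WM/CSF shells and WM lesions."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    naa_gm: float = 30.0
    naa_wm: float = 25.0
    naa_lesion: float = 20.0
    naa_csf: float = 0.0
    lesion_load: str = "mild"
    noise_sigma: float = 2.0
    seed: int = 0
    # clinical MS lesion diameters run ~3-15 mm; these radii (in voxels at
    # 1 mm) give lesions whose cores are resolved on the x2-coarser grid
    lesion_radius_range: tuple[float, float] = (2.5, 5.5)
    # "1% noise level" of the simulated MR sequences, relative to the
    # brightest tissue of each contrast
    t1_noise_sigma: float = 1.4
    flair_noise_sigma: float = 1.9

    def __post_init__(self) -> None:
        if min(self.naa_gm, self.naa_wm, self.naa_lesion) <= 0:
            raise ValueError("tissue concentrations must be positive")
        if self.lesion_load not in LESION_LOAD_PRESETS:
            raise ValueError(
                f"lesion_load must be one of {sorted(LESION_LOAD_PRESETS)}"
            )


@dataclasses.dataclass
class AcquisitionConfig:
    """Noise + anti-alias filtering + decimation of a high-resolution map.

    ``filter_order`` is the number of taps of the symmetric (zero-phase)
    equiripple FIR anti-alias filter; ``filter_ripple_db`` the passband
    ripple target of the minimax design.  The filter is normalized to unit
    DC gain, so constants pass through exactly.
    """

    decimation: tuple[int, int, int] = (2, 2, 2)
    filter_order: int = 31
    filter_ripple_db: float = 0.1
    noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.decimation = tuple(int(f) for f in self.decimation)  # type: ignore[assignment]
        if any(f < 1 for f in self.decimation):
            raise ValueError("decimation factors must be >= 1")
        if self.filter_order < 1:
            raise ValueError("filter order must be >= 1")
        if self.filter_order % 2 == 0:
            raise ValueError("filter length must be odd (symmetric, zero-phase)")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")


# ---------------------------------------------------------------------------
# Phantoms
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CylinderPhantom:
    labels: VolumeGrid  # integer compartment labels (0 water, 1..n cylinders)
    ace: VolumeGrid  # ground-truth acetate map, mM
    t1: VolumeGrid  # T1-like intensity volume
    config: CylinderPhantomConfig


@dataclasses.dataclass
class BrainPhantom:
    probs: TissueProbMaps
    lesions: LesionMask
    t1: VolumeGrid
    flair: VolumeGrid
    naa: VolumeGrid  # ground-truth NAA map, a.u.
    config: BrainPhantomConfig


def make_cylinder_phantom(config: CylinderPhantomConfig | None = None) -> CylinderPhantom:
    """Build the multi-cylinder phantom on its high-resolution grid.

    The acetate map is exactly piecewise constant per compartment; the
    T1-like volume gives every compartment a distinct constant intensity so
    the anatomy channel carries the compartment boundaries.
    """
    if config is None:
        config = CylinderPhantomConfig()
    fov = config.outer_diameter_mm + 2.0 * config.fov_margin_mm
    n_xy = int(round(fov / config.hr_spacing_mm))
    shape = (n_xy, n_xy, config.n_slices)
    spacing = (config.hr_spacing_mm, config.hr_spacing_mm, config.slice_thickness_mm)
    # voxel centers, phantom axis through the world origin
    cx = (np.arange(n_xy) - (n_xy - 1) / 2.0) * spacing[0]
    xg, yg = np.meshgrid(cx, cx, indexing="ij")

    labels2d = np.zeros((n_xy, n_xy), dtype=np.int16)
    r_cyl = config.cylinder_diameter_mm / 2.0
    for i in range(config.n_cylinders):
        ang = -math.pi / 2.0 + 2.0 * math.pi * i / config.n_cylinders
        ox = config.ring_radius_mm * math.cos(ang)
        oy = config.ring_radius_mm * math.sin(ang)
        inside = (xg - ox) ** 2 + (yg - oy) ** 2 <= r_cyl**2
        labels2d[inside] = i + 1

    labels = np.repeat(labels2d[:, :, None], config.n_slices, axis=2)
    conc = config.concentrations
    ace = conc[labels]
    # distinct constant T1 intensity per compartment (water 100)
    t1_levels = np.concatenate([[100.0], 150.0 + 12.0 * np.arange(config.n_cylinders)])
    t1 = t1_levels[labels]

    origin = [-(n - 1) / 2.0 * s for n, s in zip(shape, spacing)]
    mk = lambda data, units: VolumeGrid.from_spacing(data, spacing, origin, units)
    return CylinderPhantom(
        labels=mk(labels, "label"),
        ace=mk(ace.astype(float), "mM"),
        t1=mk(t1.astype(float), "a.u."),
        config=config,
    )


def labels_to_probabilities(labels: VolumeGrid, n_classes: int | None = None) -> TissueProbMaps:
    """One-hot membership maps from an integer label volume."""
    lab = np.asarray(labels.data).astype(int)
    if n_classes is None:
        n_classes = int(lab.max()) + 1
    probs = np.stack([(lab == k).astype(float) for k in range(n_classes)])
    names = tuple(f"compartment_{k}" for k in range(n_classes))
    return TissueProbMaps(probs, labels.affine, names)


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def make_brain_phantom(config: BrainPhantomConfig | None = None) -> BrainPhantom:
    """Build the brain-like phantom.

    Geometry: nested ellipsoids give a WM core, a GM shell and a thin CSF rim
    with smooth (soft) transitions; per-voxel GM+WM+CSF sums to 1 inside the
    head and decays to 0 outside.  Lesions are spherical blobs seeded at
    random deep-WM voxels (reproducible under ``seed``); inside a lesion the
    NAA value is overridden to ``naa_lesion`` and the FLAIR-like volume is
    hyperintense.  The NAA ground truth is otherwise the membership-weighted
    mixture sum_k p_k c_k.
    """
    if config is None:
        config = BrainPhantomConfig()
    shape = config.shape
    rng = np.random.default_rng(config.seed)

    idx = np.indices(shape, dtype=float)
    center = [(n - 1) / 2.0 for n in shape]
    semi = [0.46 * shape[0], 0.42 * shape[1], 0.44 * shape[2]]
    rho = np.sqrt(sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3)))

    def edge(rho0: float, width: float) -> np.ndarray:
        return _smoothstep((rho - rho0) / width + 0.5)

    s_wm = edge(0.62, 0.10)   # WM core -> GM
    s_gm = edge(0.86, 0.08)   # GM -> CSF
    s_out = edge(0.98, 0.06)  # CSF -> outside
    p_wm = 1.0 - s_wm
    p_gm = s_wm - s_gm
    p_csf = s_gm - s_out
    probs = np.stack([p_gm, p_wm, p_csf])

    n_lesions = LESION_LOAD_PRESETS[config.lesion_load]
    # MS lesions are periventricular / deep white matter: seed well inside
    # the WM core so the surrounding-WM ring is not contaminated by cortex
    core = np.argwhere((p_wm > 0.99) & (rho < 0.4))
    if core.size == 0:
        raise ValueError("no white matter present to seed lesions in")
    lesion = np.zeros(shape, dtype=bool)
    centers = core[rng.choice(len(core), size=n_lesions, replace=False)]
    rlo, rhi = config.lesion_radius_range
    for c in centers:
        rad = rng.uniform(rlo, rhi)
        d2 = sum((idx[a] - c[a]) ** 2 for a in range(3))
        lesion |= d2 <= rad**2
    lesion &= p_wm > 0.5  # lesions live in white matter

    # the segmenter treats lesions as an outlier class: lesion voxels carry
    # no membership in the normal GM/WM/CSF maps (they are covered by the
    # binary lesion segmentation instead)
    probs[:, lesion] = 0.0

    naa = (
        config.naa_gm * p_gm + config.naa_wm * p_wm + config.naa_csf * p_csf
    )
    naa[lesion] = config.naa_lesion

    t1 = 95.0 * p_gm + 140.0 * p_wm + 35.0 * p_csf
    t1[lesion] = 105.0  # MS lesions mildly T1-hypointense vs WM
    flair = 125.0 * p_gm + 100.0 * p_wm + 15.0 * p_csf
    flair[lesion] = 190.0  # FLAIR hyperintensity
    if config.t1_noise_sigma > 0:
        t1 = t1 + rng.normal(0.0, config.t1_noise_sigma, size=shape)
    if config.flair_noise_sigma > 0:
        flair = flair + rng.normal(0.0, config.flair_noise_sigma, size=shape)

    spacing = config.spacing_mm
    origin = [-(n - 1) / 2.0 * s for n, s in zip(shape, spacing)]
    mk = lambda data, units: VolumeGrid.from_spacing(data, spacing, origin, units)
    affine = mk(naa, "").affine
    return BrainPhantom(
        probs=TissueProbMaps(probs, affine, ("GM", "WM", "CSF")),
        lesions=LesionMask(lesion, affine),
        t1=mk(t1, "a.u."),
        flair=mk(flair, "a.u."),
        naa=mk(naa, "a.u."),
        config=config,
    )


# ---------------------------------------------------------------------------
# Acquisition simulator
# ---------------------------------------------------------------------------

def _decimate_axis(x: np.ndarray, axis: int, factor: int) -> np.ndarray:
    """Sample the filtered signal at block centers f*p + (f-1)/2 along one
    axis, linearly interpolating when the center is fractional."""
    n_lr = x.shape[axis] // factor
    pos = np.arange(n_lr) * factor + (factor - 1) / 2.0
    lo = np.floor(pos).astype(int)
    frac = pos - lo
    a = np.take(x, lo, axis=axis)
    if np.all(frac == 0):
        return a
    b = np.take(x, np.minimum(lo + 1, x.shape[axis] - 1), axis=axis)
    sh = [1] * x.ndim
    sh[axis] = n_lr
    f = frac.reshape(sh)
    return (1.0 - f) * a + f * b


def antialias_taps(factor: int, n_taps: int = 31, ripple_db: float = 0.1) -> np.ndarray:
    """Symmetric FIR anti-alias low-pass for decimation by ``factor``.

    Minimax (Chebyshev-approximation) design with the transition band
    centered on the target Nyquist frequency 1/(2*factor) -- the canonical
    decimation-filter corner placement (a 6 dB point at the new Nyquist);
    taps are normalized to unit sum so the DC gain is exactly 1.
    """
    if factor < 2:
        raise ValueError("anti-alias filter needs a decimation factor >= 2")
    nyq_t = 0.5 / factor  # target Nyquist, sampling frequency = 1
    if nyq_t >= 0.5:
        raise ValueError("filter cutoff must be below the Nyquist frequency")
    delta_p = 10.0 ** (ripple_db / 20.0) - 1.0
    taps = signal.remez(
        n_taps,
        [0.0, 0.8 * nyq_t, 1.2 * nyq_t, 0.5],
        [1.0, 0.0],
        weight=[1.0, 1.0 / max(delta_p, 1e-6)],
        fs=1.0,
    )
    return taps / taps.sum()


def simulate_acquisition(hr_map: VolumeGrid, config: AcquisitionConfig) -> VolumeGrid:
    """Degrade a high-resolution map to a low-resolution acquisition.

    Gaussian noise (standard deviation ``noise_sigma``) is added to the
    high-resolution map, each axis with a decimation factor > 1 is low-pass
    filtered with the zero-phase FIR of :func:`antialias_taps` (edge-value
    extension at the boundaries), and the result is decimated.  The returned
    affine places each low-resolution voxel at the center of its source
    block, so the output is exactly nested under the input grid.
    """
    for n, f in zip(hr_map.shape, config.decimation):
        if n % f != 0:
            raise ValueError(
                f"shape {hr_map.shape} not divisible by decimation {config.decimation}"
            )
    rng = np.random.default_rng(config.seed)
    x = np.asarray(hr_map.data, dtype=float)
    if config.noise_sigma > 0:
        x = x + rng.normal(0.0, config.noise_sigma, size=x.shape)
    else:
        x = x.copy()

    for axis, f in enumerate(config.decimation):
        if f == 1:
            continue
        taps = antialias_taps(f, config.filter_order, config.filter_ripple_db)
        x = ndimage.convolve1d(x, taps, axis=axis, mode="nearest")
        x = _decimate_axis(x, axis, f)

    scale = np.eye(4)
    scale[:3, :3] = np.diag(config.decimation)
    scale[:3, 3] = (np.asarray(config.decimation, dtype=float) - 1.0) / 2.0
    return VolumeGrid(x, hr_map.affine @ scale, hr_map.units)
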