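"""Iterative patch-based super-resolution of metabolite maps.

The algorithm upsamples a low-resolution metabolite map y onto a grid with
``scale`` times more voxels per axis and then alternates two steps until the
map stops changing:

*reconstruction* -- every high-resolution voxel x_i is replaced by a convex
combination of the voxels x_j in a cubic search volume around it,

    E(x_i | zeta_i) = sum_j [(1 - alpha_i) w_MRI(x_i,x_j)
                             + alpha_i w_MRSI(x_i,x_j)] x_j ,

where the MRSI weights are classic non-local-means weights computed from
patches of the metabolite map itself,

    w_MRSI(x_i,x_j) prop. exp( -||N_i - N_j||^2 / (2 N h_i^2) ),

and the MRI weights additionally gate each candidate by how much tissue the
two voxels share, using soft GM/WM/CSF memberships p and patches taken from
the high-resolution anatomical channels (T1-weighted, FLAIR),

    w_MRI(x_i,x_j) prop. (1/K) sum_k p_{i,k} p_{j,k}
                         exp( -||N_i - N_j||^2 / (2 N h_i^2) ).

alpha is 1 inside lesions (reconstruction driven by the metabolite map alone,
because anatomy underestimates metabolic abnormality there) and 0 elsewhere.
The per-voxel noise scale h_i is estimated from pseudo-residuals against the
6-neighborhood mean.

*mean correction* -- data consistency with the acquisition: the current
estimate is convolved with the (sinc-shaped) point-spread function, averaged
over each ``scale``-block to emulate a low-resolution voxel, and the residual
against the measured value is added back to every voxel of the block:

    x_i <- x_i + (y_p - H(x)_p)  for every i in block p.

With an identity PSF this makes every block mean match y exactly.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy.ndimage import convolve1d, correlate1d

from . import baselines
from .grids import LesionMask, TissueProbMaps, VolumeGrid, resample_to_grid

__all__ = [
    "PSFModel",
    "PBSRConfig",
    "NoiseField",
    "PBSRResult",
    "initialize_hr",
    "pseudo_residual_noise",
    "local_patch_sd",
    "mrsi_weights",
    "mri_weights",
    "alpha_field",
    "reconstruct_pass",
    "sinc_psf_kernel",
    "mean_correction",
    "run_pbsr",
]

_TAU = 1e-12  # stabilizer in the relative-change convergence metric


# ---------------------------------------------------------------------------
# Configuration containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PSFModel:
    """Separable sinc point-spread function of phase-encoded MRSI.

    ``nominal_voxel_size`` is the low-resolution voxel size in mm per axis
    (field of view / number of phase-encoding steps); ``None`` means "take it
    from the low-resolution map at run time".  The kernel samples
    sinc(d / nominal) at high-resolution voxel offsets d, truncated at
    ``kernel_truncation`` low-resolution voxels (two sinc lobes by default)
    and normalized to unit sum.
    """

    nominal_voxel_size: tuple[float, float, float] | None = None
    kernel_truncation: float = 2.0
    normalize: bool = True


@dataclasses.dataclass
class PBSRConfig:
    """All tunables of the super-resolution algorithm.

    patch_size is the edge length of the patch cube N_i (8 voxels, spanning
    offsets [-4, +3] about the center); search_radius is the half-width of
    the search volume zeta_i (5 -> an 11^3 cube); conv_tol is the relative
    L2 change between iterates below which iteration stops; h_floor is the
    minimum allowed noise scale (None -> 1e-6 x the median absolute map
    value, guarding against division by zero on locally constant images).
    """

    scale: tuple[int, int, int] = (2, 2, 2)
    patch_size: int = 8
    search_radius: int = 5
    alpha_policy: str = "lesion_binary"
    conv_tol: float = 1e-3
    max_iters: int = 10
    h_floor: float | None = None
    psf: PSFModel | None = dataclasses.field(default_factory=PSFModel)
    init_mode: str = "linear"

    def __post_init__(self) -> None:
        self.scale = tuple(int(s) for s in self.scale)  # type: ignore[assignment]
        if len(self.scale) != 3 or any(s < 1 for s in self.scale):
            raise ValueError("scale components must be integers >= 1")
        if self.patch_size < 2:
            raise ValueError("patch_size must be >= 2")
        if self.search_radius < 1:
            raise ValueError("search_radius must be >= 1")
        if not (0.0 < self.conv_tol < 1.0):
            raise ValueError("conv_tol must lie in (0, 1)")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.init_mode != "linear":
            raise ValueError(f"unknown init_mode {self.init_mode!r}")
        _parse_alpha_policy(self.alpha_policy)


@dataclasses.dataclass
class NoiseField:
    """Per-voxel noise standard deviation h_i on the high-resolution grid."""

    h: np.ndarray
    h_floor: float


@dataclasses.dataclass
class PBSRResult:
    """High-resolution map plus per-iteration diagnostics."""

    hr_map: VolumeGrid
    iterations: int
    rel_change_trace: list[float]
    consistency_trace: list[float]
    converged: bool


# ---------------------------------------------------------------------------
# Patch geometry helpers
# ---------------------------------------------------------------------------

def _patch_window(size: int) -> tuple[int, int]:
    """Offsets [lo, hi] of the patch cube about its center voxel.

    Even sizes have no center voxel; size 8 spans [-4, +3] per axis.
    """
    lo = -(size // 2)
    return lo, size - 1 + lo


def _boxsum(a: np.ndarray, size: int) -> np.ndarray:
    """Sum of ``a`` over the patch window at every voxel, zero-padded, using
    the same [lo, hi] window convention as :func:`_patch_window`."""
    w = np.ones(size)
    out = np.asarray(a, dtype=float)
    for axis in range(3):
        out = correlate1d(out, w, axis=axis, mode="constant", cval=0.0)
    return out


def _offset_slices(shape: Sequence[int], delta: Sequence[int]):
    """Slices (dst, src) such that arr_dst <- arr[src] realizes x[i + delta]
    over all in-bounds voxels i."""
    dst, src = [], []
    for n, d in zip(shape, delta):
        dst.append(slice(max(0, -d), n - max(0, d)))
        src.append(slice(max(0, d), n - max(0, -d)))
    return tuple(dst), tuple(src)


def _patch_counts(shape: Sequence[int], size: int) -> np.ndarray:
    """Number of in-bounds voxels of the patch window at every voxel."""
    return _boxsum(np.ones(shape), size)


def local_patch_sd(volume: VolumeGrid, config: PBSRConfig) -> NoiseField:
    """Noise scale for the anatomy-guided weights: the standard deviation of
    the channel's intensities over the patch neighborhood N_i.

    Large at tissue boundaries (tolerant weights), small in flat regions
    (only near-identical patches count); floored like the pseudo-residual
    estimate so noiseless flat anatomy does not divide by zero.
    """
    x = np.asarray(volume.data, dtype=float)
    cnt = _patch_counts(x.shape, config.patch_size)
    mean = _boxsum(x, config.patch_size) / cnt
    var = np.maximum(_boxsum(x * x, config.patch_size) / cnt - mean**2, 0.0)
    floor = config.h_floor
    if floor is None:
        floor = 1e-6 * float(np.median(np.abs(x)))
    if floor <= 0.0:
        floor = 1e-12
    return NoiseField(h=np.maximum(np.sqrt(var), floor), h_floor=floor)


def _parse_alpha_policy(policy: str) -> float | None:
    if policy == "lesion_binary":
        return None
    if policy.startswith("constant:"):
        v = float(policy.split(":", 1)[1])
        if not (0.0 <= v <= 1.0):
            raise ValueError("constant alpha must lie in [0, 1]")
        return v
    raise ValueError(f"unknown alpha policy {policy!r}")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def initialize_hr(lr_map: VolumeGrid, scale: Sequence[int]) -> VolumeGrid:
    """Linear upsampling of the low-resolution map onto the nested
    high-resolution grid (shape x scale, spacing / scale)."""
    return baselines.upsample_linear(lr_map, scale)


def pseudo_residual_noise(volume: VolumeGrid, config: PBSRConfig) -> NoiseField:
    """Estimate the per-voxel noise scale h_i from pseudo-residuals.

    eps_i = sqrt(6/7) (x_i - mean of the 6-neighborhood); h_i^2 is the mean
    of eps^2 over the voxels of the search volume around i (the candidates
    contributing to x_i's reconstruction), floored at ``h_floor``.  Boundary
    voxels use whichever of the six neighbors exist.
    """
    x = np.asarray(volume.data, dtype=float)
    if x.size == 0:
        raise ValueError("empty map")
    if min(x.shape) < 2:
        raise ValueError("map must have at least 2 voxels per axis")
    nb_sum = np.zeros_like(x)
    nb_cnt = np.zeros_like(x)
    for axis in range(3):
        for d in (-1, 1):
            delta = [0, 0, 0]
            delta[axis] = d
            dst, src = _offset_slices(x.shape, delta)
            nb_sum[dst] += x[src]
            nb_cnt[dst] += 1.0
    eps = math.sqrt(6.0 / 7.0) * (x - nb_sum / nb_cnt)

    w = 2 * config.search_radius + 1
    h2 = _boxsum(eps**2, w) / _boxsum(np.ones_like(x), w)

    floor = config.h_floor
    if floor is None:
        floor = 1e-6 * float(np.median(np.abs(x)))
    if floor <= 0.0:
        floor = 1e-12
    h = np.maximum(np.sqrt(h2), floor)
    return NoiseField(h=h, h_floor=floor)


def _search_candidates(
    center: Sequence[int], shape: Sequence[int], radius: int
) -> np.ndarray:
    """All in-bounds voxel indices of the cubic search volume, as (M, 3)."""
    ranges = [
        np.arange(max(0, c - radius), min(n, c + radius + 1))
        for c, n in zip(center, shape)
    ]
    grid = np.meshgrid(*ranges, indexing="ij")
    return np.stack([g.ravel() for g in grid], axis=1)


def _pair_patch_stats(
    x: np.ndarray, i: Sequence[int], j: Sequence[int], size: int
) -> tuple[float, int]:
    """Squared patch distance and overlap count for the voxel pair (i, j),
    truncating the patch to offsets where both patches are in bounds."""
    lo, hi = _patch_window(size)
    sl_i, sl_j = [], []
    count = 1
    for a in range(3):
        t_lo = max(lo, -i[a], -j[a])
        t_hi = min(hi, x.shape[a] - 1 - i[a], x.shape[a] - 1 - j[a])
        sl_i.append(slice(i[a] + t_lo, i[a] + t_hi + 1))
        sl_j.append(slice(j[a] + t_lo, j[a] + t_hi + 1))
        count *= t_hi - t_lo + 1
    d = x[tuple(sl_i)] - x[tuple(sl_j)]
    return float(np.sum(d * d)), count


def mrsi_weights(
    center: Sequence[int],
    search: np.ndarray | None,
    volume: VolumeGrid,
    noise: NoiseField,
    config: PBSRConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized non-local-means weights of one voxel over its search volume.

    Returns ``(candidates, weights)`` where candidates is an (M, 3) index
    array and the weights sum to 1.
    """
    x = np.asarray(volume.data, dtype=float)
    center = tuple(int(c) for c in center)
    if search is None:
        search = _search_candidates(center, x.shape, config.search_radius)
    h2 = float(noise.h[center]) ** 2
    w = np.empty(len(search))
    for m, j in enumerate(search):
        s, n = _pair_patch_stats(x, center, tuple(int(v) for v in j), config.patch_size)
        w[m] = math.exp(-s / (2.0 * n * h2))
    total = w.sum()
    if total <= 0.0:
        raise RuntimeError("degenerate MRSI weights (flooring should prevent this)")
    return search, w / total


def mri_weights(
    center: Sequence[int],
    search: np.ndarray | None,
    mri_channels: Sequence[VolumeGrid],
    probs: TissueProbMaps,
    noises: Sequence[NoiseField],
    config: PBSRConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Anatomy-guided weights of one voxel over its search volume.

    Candidates sharing no tissue class with the center receive weight exactly
    0.  With several anatomical channels the patch distance is the
    channel-concatenated distance, each channel scaled by its own noise
    scale (the local patch SD of that channel, see :func:`local_patch_sd`).
    The weights sum to 1; if every candidate has zero tissue overlap the
    unnormalized zeros are returned as-is.
    """
    if len(mri_channels) != len(noises):
        raise ValueError("one noise field per anatomical channel is required")
    shape = mri_channels[0].shape
    if probs.shape != shape:
        raise ValueError("probability maps are not on the target grid")
    center = tuple(int(c) for c in center)
    if search is None:
        search = _search_candidates(center, shape, config.search_radius)
    arrays = [np.asarray(ch.data, dtype=float) for ch in mri_channels]
    h2 = [float(nf.h[center]) ** 2 for nf in noises]
    p_center = probs.probs[(slice(None),) + center]
    k_classes = len(probs.classes)
    w = np.empty(len(search))
    for m, j in enumerate(search):
        jj = tuple(int(v) for v in j)
        dist = 0.0
        n_tot = 0
        for arr, hh in zip(arrays, h2):
            s, n = _pair_patch_stats(arr, center, jj, config.patch_size)
            dist += s / hh
            n_tot += n
        overlap = float(np.dot(p_center, probs.probs[(slice(None),) + jj]))
        w[m] = (overlap / k_classes) * math.exp(-dist / (2.0 * n_tot))
    total = w.sum()
    if total > 0.0:
        w = w / total
    return search, w


def alpha_field(lesions: LesionMask | None, policy: str) -> np.ndarray:
    """Per-voxel blending weight between the MRI and MRSI weight families.

    ``lesion_binary``: alpha = 1 inside lesions (MRSI-driven), 0 elsewhere
    (MRI-driven).  ``constant:v``: uniform alpha = v.
    """
    const = _parse_alpha_policy(policy)
    if const is not None:
        if lesions is None:
            raise ValueError("constant alpha policy still requires a grid-shaped mask")
        return np.full(lesions.shape, const, dtype=float)
    if lesions is None:
        raise ValueError("lesion_binary policy requires a lesion mask")
    return lesions.data.astype(float)


def reconstruct_pass(
    hr_map: VolumeGrid,
    mri_channels: Sequence[VolumeGrid],
    probs: TissueProbMaps,
    alpha: np.ndarray,
    config: PBSRConfig,
) -> VolumeGrid:
    """One full reconstruction sweep: every voxel is replaced by its
    weighted search-volume average (alpha-blended MRI/MRSI weights).

    Vectorized over voxels by iterating over search-volume *offsets*: for a
    fixed offset delta the patch distance between every voxel i and its
    candidate i+delta is a box-filtered squared difference image, so each
    offset costs a few separable filters instead of a per-voxel loop.
    Voxels whose tissue memberships are all zero (outside every class) have
    no MRI weight mass and fall back to the MRSI weights.
    """
    x = np.asarray(hr_map.data, dtype=float)
    shape = x.shape
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != shape or probs.shape != shape:
        raise ValueError("alpha / probability maps must match the map shape")
    for ch in mri_channels:
        if ch.shape != shape:
            raise ValueError("anatomical channels must match the map shape")
    if alpha.min() < 0.0 or alpha.max() > 1.0:
        raise ValueError("alpha must lie in [0, 1]")

    ps = config.patch_size
    r = config.search_radius
    k_classes = len(probs.classes)
    n_ch = len(mri_channels)

    h2_mrsi = pseudo_residual_noise(hr_map, config).h ** 2
    ch_arrays = [np.asarray(ch.data, dtype=float) for ch in mri_channels]
    ch_h2 = [local_patch_sd(ch, config).h ** 2 for ch in mri_channels]
    p = probs.probs

    need_mrsi = bool(alpha.max() > 0.0)
    z_mri = np.zeros(shape)
    a_mri = np.zeros(shape)
    z_srs = np.zeros(shape)
    a_srs = np.zeros(shape)

    offsets = range(-r, r + 1)
    for dx in offsets:
        for dy in offsets:
            for dz in offsets:
                delta = (dx, dy, dz)
                dst, src = _offset_slices(shape, delta)
                valid = np.zeros(shape)
                valid[dst] = 1.0
                n_eff = _boxsum(valid, ps)  # patch overlap count per voxel
                xj = np.zeros(shape)
                xj[dst] = x[src]

                # MRI weights: concatenated channel distance + tissue overlap
                expo = np.zeros(shape)
                for arr, hh in zip(ch_arrays, ch_h2):
                    d = np.zeros(shape)
                    d[dst] = arr[dst] - arr[src]
                    expo += _boxsum(d * d, ps) / hh
                with np.errstate(divide="ignore", invalid="ignore"):
                    expo = np.where(n_eff > 0, expo / (2.0 * n_ch * n_eff), 0.0)
                overlap = np.zeros(shape)
                for k in range(k_classes):
                    overlap[dst] += p[k][dst] * p[k][src]
                u_mri = (overlap / k_classes) * np.exp(-expo) * valid
                z_mri += u_mri
                a_mri += u_mri * xj

                if need_mrsi:
                    d = np.zeros(shape)
                    d[dst] = x[dst] - x[src]
                    s = _boxsum(d * d, ps)
                    with np.errstate(divide="ignore", invalid="ignore"):
                        e = np.where(n_eff > 0, s / (2.0 * n_eff * h2_mrsi), 0.0)
                    u_srs = np.exp(-e) * valid
                    z_srs += u_srs
                    a_srs += u_srs * xj
    no_mri = z_mri <= 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        r_mri = np.where(no_mri, 0.0, a_mri / np.where(no_mri, 1.0, z_mri))
    if need_mrsi:
        r_srs = a_srs / z_srs  # z_srs >= self-weight exp(0) = 1
        out = (1.0 - alpha) * r_mri + alpha * r_srs
        out = np.where(no_mri, r_srs, out)
    else:
        out = r_mri
        if np.any(no_mri):
            # isolated background voxels: fall back to self-similarity weights
            noise = NoiseField(np.sqrt(h2_mrsi), 0.0)
            for idx in np.argwhere(no_mri):
                cand, w = mrsi_weights(idx, None, hr_map, noise, config)
                out[tuple(idx)] = float(w @ x[tuple(cand.T)])
    return VolumeGrid(out, hr_map.affine.copy(), hr_map.units)


def sinc_psf_kernel(
    psf: PSFModel,
    hr_spacing: Sequence[float],
    lr_spacing: Sequence[float] | None = None,
) -> list[np.ndarray]:
    """Separable 1-D sinc kernels sampled at high-resolution voxel offsets.

    Each kernel samples sinc(d / nominal_voxel_size) at offsets d = m * hr
    spacing, truncated at ``kernel_truncation`` low-resolution voxels, then
    normalized to unit sum (the raw kernel is zero at d = nominal, the first
    sinc zero).
    """
    nominal = psf.nominal_voxel_size
    if nominal is None:
        if lr_spacing is None:
            raise ValueError("nominal voxel size unset and no LR spacing given")
        nominal = tuple(float(v) for v in lr_spacing)
    kernels = []
    for nom, dx in zip(nominal, hr_spacing):
        if nom <= 0:
            raise ValueError("nominal voxel size must be positive")
        m = int(np.floor(psf.kernel_truncation * nom / dx + 1e-9))
        if m < 1:
            raise ValueError(
                "high-resolution spacing does not fit inside the PSF window"
            )
        d = np.arange(-m, m + 1) * dx
        k = np.sinc(d / nom)  # np.sinc(t) = sin(pi t)/(pi t)
        if psf.normalize:
            k = k / k.sum()
        kernels.append(k)
    return kernels


def _forward_operator(
    hr_data: np.ndarray,
    config: PBSRConfig,
    hr_spacing: Sequence[float],
    lr_spacing: Sequence[float],
) -> np.ndarray:
    """H(x): PSF convolution followed by block averaging over scale-blocks."""
    x = np.asarray(hr_data, dtype=float)
    if config.psf is not None:
        kernels = sinc_psf_kernel(config.psf, hr_spacing, lr_spacing)
        for axis, k in enumerate(kernels):
            x = convolve1d(x, k, axis=axis, mode="reflect")
    s = config.scale
    new_shape = []
    for n, f in zip(x.shape, s):
        new_shape += [n // f, f]
    return x.reshape(new_shape).mean(axis=(1, 3, 5))


def mean_correction(
    hr_map: VolumeGrid, lr_map: VolumeGrid, config: PBSRConfig
) -> VolumeGrid:
    """Project the estimate back onto the measured low-resolution data.

    Adds the residual y_p - H(x)_p to every high-resolution voxel inside
    block p.  With the PSF disabled the corrected block means equal y exactly.
    """
    s = config.scale
    if tuple(hr_map.shape) != tuple(n * f for n, f in zip(lr_map.shape, s)):
        raise ValueError(
            f"high-res shape {hr_map.shape} is not scale x low-res shape "
            f"{lr_map.shape} at scale {s}"
        )
    hx = _forward_operator(hr_map.data, config, hr_map.spacing, lr_map.spacing)
    residual = np.asarray(lr_map.data, dtype=float) - hx
    up = residual
    for axis, f in enumerate(s):
        up = np.repeat(up, f, axis=axis)
    return VolumeGrid(
        np.asarray(hr_map.data, dtype=float) + up,
        hr_map.affine.copy(),
        hr_map.units,
    )


def _project_to_grid(
    source, target: VolumeGrid, mode: str, override_affine: np.ndarray | None
):
    """Resample an anatomy volume/probability/mask object onto ``target``."""
    if isinstance(source, TissueProbMaps):
        affine = override_affine if override_affine is not None else source.affine
        if source.shape == target.shape and np.allclose(affine, target.affine, atol=1e-6):
            return source
        maps = [
            resample_to_grid(
                VolumeGrid(p, affine), target, mode="linear", pad_value=0.0
            ).data
            for p in source.probs
        ]
        return TissueProbMaps(np.clip(np.stack(maps), 0.0, 1.0), target.affine, source.classes)
    if isinstance(source, LesionMask):
        affine = override_affine if override_affine is not None else source.affine
        if source.shape == target.shape and np.allclose(affine, target.affine, atol=1e-6):
            return source
        vol = resample_to_grid(
            VolumeGrid(source.data.astype(float), affine), target,
            mode="nearest", pad_value=0.0,
        )
        return LesionMask(vol.data > 0.5, target.affine)
    affine = override_affine if override_affine is not None else source.affine
    src = VolumeGrid(source.data, affine, source.units)
    if src.same_geometry(target):
        return src
    return resample_to_grid(src, target, mode=mode, pad_value=0.0)


def run_pbsr(
    lr_map: VolumeGrid,
    t1: VolumeGrid,
    flair: VolumeGrid | None,
    probs: TissueProbMaps,
    lesions: LesionMask | None,
    mri_affine: np.ndarray | None = None,
    mrsi_affine: np.ndarray | None = None,
    config: PBSRConfig | None = None,
) -> PBSRResult:
    """Full super-resolution pipeline.

    Initializes by linear upsampling, projects the anatomical channels,
    tissue probabilities and lesion mask onto the high-resolution grid
    (intensities and probabilities linearly, masks nearest-neighbor), then
    alternates :func:`reconstruct_pass` and :func:`mean_correction` until the
    relative change ||x_t - x_{t-1}|| / ||x_{t-1}|| drops below ``conv_tol``
    or ``max_iters`` is reached.  Non-convergence is reported in the result,
    not raised.  ``mri_affine`` / ``mrsi_affine``, when given, override the
    affines stored in the anatomy volumes and the low-resolution map
    (scanner-supplied transforms).
    """
    if config is None:
        config = PBSRConfig()
    if mrsi_affine is not None:
        lr_map = VolumeGrid(lr_map.data, mrsi_affine, lr_map.units)

    hr = initialize_hr(lr_map, config.scale)
    channels = [_project_to_grid(t1, hr, "linear", mri_affine)]
    if flair is not None:
        channels.append(_project_to_grid(flair, hr, "linear", mri_affine))
    probs_hr = _project_to_grid(probs, hr, "linear", mri_affine)
    lesions_hr = (
        _project_to_grid(lesions, hr, "nearest", mri_affine)
        if lesions is not None
        else LesionMask(np.zeros(hr.shape, dtype=bool), hr.affine)
    )
    alpha = alpha_field(lesions_hr, config.alpha_policy)

    rel_trace: list[float] = []
    resid_trace: list[float] = []
    converged = False
    iterations = 0
    prev = hr
    for _ in range(config.max_iters):
        iterations += 1
        rec = reconstruct_pass(prev, channels, probs_hr, alpha, config)
        cur = mean_correction(rec, lr_map, config)
        rel = float(
            np.linalg.norm(cur.data - prev.data)
            / (np.linalg.norm(prev.data) + _TAU)
        )
        hx = _forward_operator(cur.data, config, cur.spacing, lr_map.spacing)
        resid_trace.append(float(np.linalg.norm(lr_map.data - hx)))
        rel_trace.append(rel)
        prev = cur
        if rel <= config.conv_tol:
            converged = True
            break
    return PBSRResult(
        hr_map=prev,
        iterations=iterations,
        rel_change_trace=rel_trace,
        consistency_trace=resid_trace,
        converged=converged,
    )
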