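"""Conventional upsamplers used as comparison methods.

Nearest-neighbor (NN), trilinear (LIN) and cubic B-spline (BS) interpolation
onto the same high-resolution grid as the patch-based method, so that all
methods are compared voxel for voxel.  The new grid has shape
``lr_shape * scale`` and spacing ``lr_spacing / scale``; high-resolution voxel
``k`` sits at continuous low-resolution index ``(k + 0.5)/s - 0.5``, which
keeps every low-resolution voxel exactly nested over a ``scale``-sized block
of high-resolution voxels.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import ndimage

from .grids import VolumeGrid

__all__ = [
    "hr_geometry",
    "upsample_nn",
    "upsample_linear",
    "upsample_bspline3",
    "upsample",
]


def _check_scale(scale: Sequence[int]) -> tuple[int, int, int]:
    s = tuple(int(f) for f in scale)
    if len(s) != 3 or any(f < 1 for f in s) or any(
        abs(f - float(g)) > 0 for f, g in zip(s, scale)
    ):
        raise ValueError(f"scale must be three positive integers, got {scale!r}")
    return s  # type: ignore[return-value]


def hr_geometry(lr_map: VolumeGrid, scale: Sequence[int]) -> tuple[tuple, np.ndarray]:
    """Shape and affine of the upsampled grid nested in ``lr_map``."""
    s = _check_scale(scale)
    shape = tuple(n * f for n, f in zip(lr_map.shape, s))
    t = np.eye(4)
    t[:3, :3] = np.diag([1.0 / f for f in s])
    t[:3, 3] = [0.5 / f - 0.5 for f in s]
    return shape, lr_map.affine @ t


def _source_coords(shape: tuple, scale: tuple) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    for a, f in enumerate(scale):
        idx[a] = (idx[a] + 0.5) / f - 0.5
    return idx.reshape(3, -1)


def _upsample(lr_map: VolumeGrid, scale: Sequence[int], order: int,
              prefilter: bool) -> VolumeGrid:
    s = _check_scale(scale)
    shape, affine = hr_geometry(lr_map, s)
    coords = _source_coords(shape, s)
    out = ndimage.map_coordinates(
        np.asarray(lr_map.data, dtype=float),
        coords,
        order=order,
        mode="nearest",  # edge-value extension
        prefilter=prefilter,
    ).reshape(shape)
    return VolumeGrid(out, affine, lr_map.units)


def upsample_nn(lr_map: VolumeGrid, scale: Sequence[int]) -> VolumeGrid:
    """Nearest-neighbor upsampling: each source voxel is replicated into a
    ``scale``-sized block."""
    return _upsample(lr_map, scale, order=0, prefilter=False)


def upsample_linear(lr_map: VolumeGrid, scale: Sequence[int]) -> VolumeGrid:
    """Trilinear interpolation at the new voxel centers."""
    return _upsample(lr_map, scale, order=1, prefilter=False)


def upsample_bspline3(lr_map: VolumeGrid, scale: Sequence[int]) -> VolumeGrid:
    """Cubic B-spline interpolation with prefiltering, so the stored samples
    are interpolated exactly (not merely smoothed)."""
    return _upsample(lr_map, scale, order=3, prefilter=True)


_METHODS = {
    "nn": upsample_nn,
    "linear": upsample_linear,
    "bspline": upsample_bspline3,
}


def upsample(lr_map: VolumeGrid, scale: Sequence[int], method: str) -> VolumeGrid:
    """Dispatch to one of the baseline upsamplers by name."""
    try:
        fn = _METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown method {method!r}; choose from {sorted(_METHODS)}"
        ) from None
    return fn(lr_map, scale)
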