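"""Volumetric grids, affine geometry and NIfTI I/O.

The package works on 3-D scalar volumes that carry their own voxel-to-world
affine (NIfTI convention: 0-based voxel indices, affine maps indices to world
coordinates at voxel centers).  This module provides the containers shared by
all other modules -- :class:`VolumeGrid`, :class:`AffineTransform`,
:class:`TissueProbMaps`, :class:`LesionMask` -- together with NIfTI reading and
writing, affine composition between the MRI and MRSI frames, grid-to-grid
resampling, and block-averaging of soft tissue probabilities down to a coarser
grid.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "AffineTransform",
    "VolumeGrid",
    "TissueProbMaps",
    "LesionMask",
    "read_volume",
    "write_volume",
    "compose_total_affine",
    "resample_to_grid",
    "downsample_probabilities",
]


@dataclasses.dataclass(frozen=True)
class AffineTransform:
    """A 4x4 homogeneous voxel/world transform.

    The last row must be (0, 0, 0, 1) and the matrix must be invertible.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got shape {m.shape}")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=1e-9):
            raise ValueError("affine last row must be (0, 0, 0, 1)")
        if abs(np.linalg.det(m[:3, :3])) < 1e-12:
            raise ValueError("affine is singular (non-invertible)")
        object.__setattr__(self, "matrix", m)

    @property
    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def __matmul__(self, other: "AffineTransform") -> "AffineTransform":
        return AffineTransform(self.matrix @ other.matrix)


@dataclasses.dataclass
class VolumeGrid:
    """A 3-D scalar field with voxel-to-world geometry.

    Parameters
    ----------
    data
        3-D array of scalar values (metabolite concentration in arbitrary
        units, or MR intensity).
    affine
        4x4 matrix mapping 0-based voxel indices to world mm coordinates at
        voxel centers.
    units
        Free-text label for the value units (e.g. ``"mM"`` or ``"a.u."``).
    """

    data: np.ndarray
    affine: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"volume must be 3-D, got a {self.data.ndim}-D array"
            )
        if min(self.data.shape) < 1:
            raise ValueError("every axis must have at least one voxel")
        self.affine = AffineTransform(self.affine).matrix
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @classmethod
    def from_spacing(
        cls,
        data: np.ndarray,
        spacing: Sequence[float],
        origin: Sequence[float] = (0.0, 0.0, 0.0),
        units: str = "",
    ) -> "VolumeGrid":
        """Build a volume on an axis-aligned grid with the given spacing."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(np.asarray(spacing, dtype=float))
        aff[:3, 3] = np.asarray(origin, dtype=float)
        return cls(data, aff, units)

    def same_geometry(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def copy(self) -> "VolumeGrid":
        return VolumeGrid(self.data.copy(), self.affine.copy(), self.units)


@dataclasses.dataclass
class TissueProbMaps:
    """Soft tissue memberships p_{i,k} on a stated grid.

    ``probs`` is a (K, X, Y, Z) array; per voxel the class probabilities are
    non-negative and sum to at most 1 (the remainder is background).
    """

    probs: np.ndarray
    affine: np.ndarray
    classes: tuple[str, ...] = ("GM", "WM", "CSF")

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 4:
            raise ValueError("probs must be a (K, X, Y, Z) array")
        if self.probs.shape[0] != len(self.classes):
            raise ValueError("number of class names must match probs axis 0")
        if self.probs.min() < -1e-9 or self.probs.max() > 1 + 1e-6:
            raise ValueError("probabilities must lie in [0, 1]")
        if np.any(self.probs.sum(axis=0) > 1 + 1e-6):
            raise ValueError("per-voxel class probabilities must sum to <= 1")
        self.affine = AffineTransform(self.affine).matrix

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.probs.shape[1:]  # type: ignore[return-value]

    def class_map(self, name: str) -> np.ndarray:
        return self.probs[self.classes.index(name)]


@dataclasses.dataclass
class LesionMask:
    """Binary per-voxel lesion indicator."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("lesion mask must be 3-D")
        self.affine = AffineTransform(self.affine).matrix

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | Path) -> VolumeGrid:
    """Read a 3-D NIfTI-1 volume.

    The affine is taken from the sform (falling back to the qform, per
    nibabel's precedence).  No resampling is performed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(
            f"{path} is a {data.ndim}-D image; expected a 3-D volume"
        )
    units = ""
    try:
        units = img.header["descrip"].item().decode("utf-8", "ignore")
    except Exception:
        pass
    return VolumeGrid(data, np.asarray(img.affine, dtype=float), units)


def write_volume(volume: VolumeGrid, path: str | Path) -> None:
    """Write a volume as NIfTI-1, storing the affine in both sform and qform."""
    img = nib.Nifti1Image(np.asarray(volume.data), volume.affine)
    img.header.set_sform(volume.affine, code=1)
    try:
        img.header.set_qform(volume.affine, code=1)
    except Exception:
        # non-orthogonal affines cannot be encoded as a quaternion; the sform
        # alone is authoritative then
        img.header.set_qform(None, code=0)
    if volume.units:
        img.header["descrip"] = volume.units.encode()[:79]
    nib.save(img, str(Path(path)))


# ---------------------------------------------------------------------------
# Affine composition and resampling
# ---------------------------------------------------------------------------

def compose_total_affine(
    mri: AffineTransform, mrsi: AffineTransform
) -> AffineTransform:
    """Compose the transform taking MRI voxel indices into MRSI voxel indices.

    Both arguments map voxel indices into the common scanner world frame; the
    result is ``MRSI_affine^-1 @ MRI_affine``.
    """
    return mrsi.inverse @ mri


def resample_to_grid(
    source: VolumeGrid,
    target: VolumeGrid,
    mode: str = "linear",
    pad_value: float = 0.0,
) -> VolumeGrid:
    """Resample ``source`` onto the geometry (shape + affine) of ``target``.

    ``mode`` is ``"nearest"`` or ``"linear"``.  Target voxels whose centers
    map outside the source field of view receive ``pad_value``.
    """
    orders = {"nearest": 0, "linear": 1}
    if mode not in orders:
        raise ValueError(f"unknown resampling mode {mode!r}")
    # voxel(target) -> world -> voxel(source)
    m = np.linalg.inv(source.affine) @ target.affine
    idx = np.indices(target.shape, dtype=float).reshape(3, -1)
    src_idx = m[:3, :3] @ idx + m[:3, 3:4]
    out = ndimage.map_coordinates(
        np.asarray(source.data, dtype=float),
        src_idx,
        order=orders[mode],
        mode="constant",
        cval=pad_value,
        prefilter=False,
    ).reshape(target.shape)
    return VolumeGrid(out, target.affine.copy(), source.units)


def _block_mean(a: np.ndarray, factors: Sequence[int]) -> np.ndarray:
    """Block-average ``a`` by integer factors; trailing partial blocks are
    averaged over the voxels present."""
    out = np.asarray(a, dtype=float)
    for axis, f in enumerate(factors):
        f = int(f)
        if f < 1:
            raise ValueError("downsampling factors must be positive integers")
        if f == 1:
            continue
        n = out.shape[axis]
        starts = np.arange(0, n, f)
        sums = np.add.reduceat(out, starts, axis=axis)
        counts = np.diff(np.append(starts, n)).astype(float)
        shape = [1] * out.ndim
        shape[axis] = len(starts)
        out = sums / counts.reshape(shape)
    return out


def downsample_probabilities(
    probs: TissueProbMaps, factor: Sequence[int]
) -> TissueProbMaps:
    """Block-average each tissue class map over ``factor``-sized blocks.

    The per-voxel class sum is preserved (block averaging is linear).  The
    returned affine places each coarse voxel at the mean position of its block.
    """
    factor = tuple(int(f) for f in factor)
    if any(f < 1 for f in factor):
        raise ValueError("downsampling factors must be positive integers")
    new = np.stack([_block_mean(p, factor) for p in probs.probs])
    scale = np.eye(4)
    scale[:3, :3] = np.diag(factor)
    scale[:3, 3] = (np.asarray(factor, dtype=float) - 1.0) / 2.0
    return TissueProbMaps(new, probs.affine @ scale, probs.classes)
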