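"""Template-space volume and mask I/O.

Everything downstream assumes voxelwise correspondence between images:
all inputs must already live on the same template grid (spatial
normalization is performed upstream, e.g. by SPM or CapAIBL, and is out
of scope here). This module defines the grid/volume/mask containers,
NIfTI reading and writing via nibabel, and the grid-compatibility check
that every multi-image operation calls before touching voxels.

Missing voxels (out-of-field, masked-out) are represented as NaN and are
excluded from every mean and from mask logic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger("centaur")

#: Default elementwise tolerance (mm) when comparing affines.
GRID_TOL_MM = 1e-3


class GridMismatchError(ValueError):
    """Raised when an operation receives images on incompatible grids."""


@dataclass(frozen=True)
class TemplateGrid:
    """Geometry of a template-space sampling grid.

    Parameters
    ----------
    shape
        Number of voxels along each axis (i, j, k).
    affine
        4x4 voxel-to-world transform; world coordinates are template
        (MNI-style) millimetres.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be three positive integers, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        """Voxel edge lengths in mm along each voxel axis."""
        return tuple(float(v) for v in np.linalg.norm(self.affine[:3, :3], axis=0))

    def world_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World (x, y, z) coordinate of every voxel, each as an array of ``shape``."""
        ii, jj, kk = np.meshgrid(*(np.arange(s) for s in self.shape), indexing="ij")
        m, t = self.affine[:3, :3], self.affine[:3, 3]
        x = m[0, 0] * ii + m[0, 1] * jj + m[0, 2] * kk + t[0]
        y = m[1, 0] * ii + m[1, 1] * jj + m[1, 2] * kk + t[1]
        z = m[2, 0] * ii + m[2, 1] * jj + m[2, 2] * kk + t[2]
        return x, y, z

    def world_z(self) -> np.ndarray:
        """World z (inferior-superior, mm) of every voxel."""
        return self.world_coords()[2]


def default_grid(shape: tuple[int, int, int] = (91, 109, 91),
                 voxel_size_mm: float = 2.0) -> TemplateGrid:
    """Conventional normalized-space grid: isotropic voxels, world origin at center.

    The default (91x109x91 at 2 mm) matches the common normalized-space
    dialect; geometry is data, not assumption, so any grid can be used.
    """
    shape = tuple(int(s) for s in shape)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -voxel_size_mm * (np.array(shape) - 1) / 2.0
    return TemplateGrid(shape=shape, affine=affine)


@dataclass(frozen=True)
class VolumeImage:
    """Scalar 3-D volume on a template grid (uptake, difference, or CTRz image).

    ``values`` is float with NaN marking missing voxels.
    """

    grid: TemplateGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {values.shape} does not match grid shape {self.grid.shape}")
        if np.isinf(values).any():
            raise ValueError("volume contains infinite values; only NaN marks missing voxels")
        object.__setattr__(self, "values", values)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())


@dataclass(frozen=True)
class BinaryMask:
    """Boolean 3-D volume on a template grid."""

    grid: TemplateGrid
    membership: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        membership = np.asarray(self.membership)
        if membership.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {membership.shape} does not match grid shape {self.grid.shape}")
        object.__setattr__(self, "membership", membership.astype(bool))

    @property
    def n_voxels(self) -> int:
        """|M|: number of member voxels."""
        return int(self.membership.sum())

    def is_empty(self) -> bool:
        return self.n_voxels == 0


def grids_compatible(a: TemplateGrid, b: TemplateGrid, tol: float = GRID_TOL_MM) -> bool:
    """True iff shapes are equal and affines agree elementwise within ``tol`` mm."""
    return a.shape == b.shape and bool(np.all(np.abs(a.affine - b.affine) <= tol))


def require_same_grid(*objs: VolumeImage | BinaryMask, tol: float = GRID_TOL_MM) -> TemplateGrid:
    """Return the shared grid, raising GridMismatchError if any pair differs.

    Downstream operations fail fast here rather than silently resampling.
    """
    if not objs:
        raise ValueError("no images given")
    grid = objs[0].grid
    for other in objs[1:]:
        if not grids_compatible(grid, other.grid, tol=tol):
            raise GridMismatchError(
                f"incompatible grids: shape {grid.shape} vs {other.grid.shape} "
                f"or affines differ beyond {tol} mm")
    return grid


def load_volume(path: str | Path) -> VolumeImage:
    """Load a single static 3-D NIfTI volume.

    Non-finite voxels are flagged missing (NaN) and their count is logged.
    4-D inputs are rejected: the framework operates on SUVR-ready static
    frames only.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 and all(s == 1 for s in data.shape[3:]) else data
    if data.ndim != 3:
        raise ValueError(
            f"expected 3-D volume, got {data.ndim}-D data in {path} "
            "(dynamic/multi-frame input is not supported)")
    values = data.astype(float)
    nonfinite = ~np.isfinite(values)
    if nonfinite.any():
        logger.warning("%s: %d non-finite voxels flagged missing", path, int(nonfinite.sum()))
        values[nonfinite] = np.nan
    grid = TemplateGrid(shape=values.shape, affine=np.asarray(img.affine, dtype=float))
    return VolumeImage(grid=grid, values=values)


def save_volume(volume: VolumeImage, path: str | Path) -> None:
    """Write a volume as NIfTI-1 (float64; missing voxels stored as NaN)."""
    img = nib.Nifti1Image(volume.values, volume.grid.affine)
    nib.save(img, str(path))


def load_mask(path: str | Path, threshold: float = 0.5) -> BinaryMask:
    """Load a mask volume; probabilistic maps are binarized at > ``threshold``.

    NaN voxels are treated as outside the mask.
    """
    vol = load_volume(path)
    membership = np.nan_to_num(vol.values, nan=0.0) > threshold
    return BinaryMask(grid=vol.grid, membership=membership)


def save_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as a 0/1 integer NIfTI volume."""
    img = nib.Nifti1Image(mask.membership.astype(np.uint8), mask.grid.affine)
    nib.save(img, str(path))
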