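"""Mask algebra: slice-bounded reference region, intersection, left-right
symmetrization, and the Dice agreement index.

The reference region for tau SUVR is the cerebellar-cortex mask restricted
to an axial slab: the upper cerebellum (world z above -37 mm) is excluded
to avoid vermis off-target binding, and the lower edge (z below -47 mm) is
excluded to avoid partial-volume, axial-sensitivity and out-of-field
scatter artifacts. Slab bounds are expressed in template-space world z
(mm), inclusive, and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .template_io import BinaryMask, TemplateGrid, require_same_grid

_AXIS_TOL = 1e-6


@dataclass(frozen=True)
class ReferenceRegionSpec:
    """Sub-cerebellar reference region: cerebellar cortex within an axial slab.

    ``z_upper``/``z_lower`` are world z bounds in mm, inclusive.
    """

    base_mask: BinaryMask
    z_upper: float = -37.0
    z_lower: float = -47.0

    def __post_init__(self) -> None:
        if not self.z_lower < self.z_upper:
            raise ValueError(f"z_lower ({self.z_lower}) must be below z_upper ({self.z_upper})")


def build_reference_region(spec: ReferenceRegionSpec) -> BinaryMask:
    """Restrict the cerebellar mask to voxels with z_lower <= world z <= z_upper."""
    if spec.base_mask.is_empty():
        raise ValueError("base cerebellar mask is empty")
    z = spec.base_mask.grid.world_z()
    slab = (z >= spec.z_lower) & (z <= spec.z_upper)
    membership = spec.base_mask.membership & slab
    if not membership.any():
        raise ValueError(
            f"reference region empty: cerebellar mask has no voxels with world z in "
            f"[{spec.z_lower}, {spec.z_upper}] mm")
    return BinaryMask(grid=spec.base_mask.grid, membership=membership)


def intersect(masks: Sequence[BinaryMask]) -> BinaryMask:
    """Voxelwise logical AND of two or more masks on a shared grid.

    The result may be empty; operations that need a nonempty mask check
    downstream.
    """
    if len(masks) < 2:
        raise ValueError("intersect requires at least 2 masks")
    grid = require_same_grid(*masks)
    membership = np.logical_and.reduce([m.membership for m in masks])
    return BinaryMask(grid=grid, membership=membership)


def union(masks: Sequence[BinaryMask]) -> BinaryMask:
    """Voxelwise logical OR of masks on a shared grid."""
    if not masks:
        raise ValueError("union requires at least 1 mask")
    grid = require_same_grid(*masks)
    membership = np.logical_or.reduce([m.membership for m in masks])
    return BinaryMask(grid=grid, membership=membership)


def _lr_axis(grid: TemplateGrid) -> int:
    """Voxel axis aligned with world x, or raise if none is."""
    m = grid.affine[:3, :3]
    for axis in range(3):
        col = m[:, axis]
        if abs(col[0]) > _AXIS_TOL and abs(col[1]) <= _AXIS_TOL and abs(col[2]) <= _AXIS_TOL:
            # no other voxel axis may contribute to world x
            others = [a for a in range(3) if a != axis]
            if all(abs(m[0, a]) <= _AXIS_TOL for a in others):
                return axis
    raise ValueError("affine has no voxel axis purely aligned with world x; cannot mirror")


def reflect(mask: BinaryMask) -> BinaryMask:
    """Left-right reflection of a mask across the world x = 0 plane.

    Requires a voxel axis aligned with world x. The reflected voxel index
    is i' = round(c) - i where c solves x(c/2) = 0, i.e. nearest-voxel
    mapping when the midplane bisects a voxel column; this map is an
    involution, so reflect(reflect(m)) == m.
    """
    axis = _lr_axis(mask.grid)
    a = mask.grid.affine[0, axis]
    b = mask.grid.affine[0, 3]
    # world x of index i along `axis` is a*i + b; reflection index i' = c - i with c = -2b/a
    c = -2.0 * b / a
    k = int(np.floor(c + 0.5))
    n = mask.grid.shape[axis]
    idx = k - np.arange(n)
    valid = (idx >= 0) & (idx < n)
    out = np.zeros(mask.grid.shape, dtype=bool)
    src = np.moveaxis(mask.membership, axis, 0)
    dst = np.moveaxis(out, axis, 0)
    dst[idx[valid]] = src[valid]
    return BinaryMask(grid=mask.grid, membership=out)


def symmetrize(mask: BinaryMask) -> BinaryMask:
    """Mirror-fuse: union of a mask with its left-right reflection.

    Fusion is a union (not intersection): the goal is to remove
    hemispheric asymmetry without discarding observed topography. The
    output is mirror-invariant and the operation idempotent.
    """
    mirrored = reflect(mask)
    return BinaryMask(grid=mask.grid, membership=mask.membership | mirrored.membership)


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice agreement index 2|A∩B| / (|A|+|B|), in [0, 1].

    Computed on voxel counts; all masks share one grid so voxel and
    volume weighting coincide.
    """
    require_same_grid(a, b)
    na, nb = a.n_voxels, b.n_voxels
    if na + nb == 0:
        raise ValueError("Dice undefined: both masks empty")
    overlap = int((a.membership & b.membership).sum())
    return 2.0 * overlap / (na + nb)
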