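"""Group-contrast tau-mask generation pipeline.

Per tracer: average the cognitively-unimpaired amyloid-negative (CU Ab-)
scans and the AD amyloid-positive (AD Ab+) scans, subtract to form a
difference image, and threshold it at a fraction (default one third) of
the mean difference inside an inferior-temporal anchor region. The
universal mask is the intersection of the tracer-specific masks,
restricted to gray matter and then mirror-fused to remove hemispheric
asymmetry. Four regional masks (mesial temporal, meta temporal,
temporo-parietal, frontal) are carved from the universal mask by
intersection with anatomical extents supplied as data.

Each builder records provenance (threshold value, voxel counts) through
``MaskProvenance`` so that masks written to disk can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .mask_ops import intersect, symmetrize
from .template_io import BinaryMask, VolumeImage, require_same_grid

DEFAULT_FRACTION = 1.0 / 3.0


@dataclass(frozen=True)
class MaskBuildConfig:
    """Parameters of the mask-generation pipeline.

    fraction
        Fraction of the inferior-temporal mean difference used as the
        threshold; default 1/3.
    it_mask
        Inferior-temporal anchor region in which the difference is summarized.
    gm_mask
        Gray-matter mask (probabilistic maps should be binarized at > 0.5
        before construction).
    subregion_atlas
        Named anatomical extents for the regional masks.
    summary
        Summary statistic of the difference over the anchor region:
        "mean" (default) or "median".
    """

    it_mask: BinaryMask
    gm_mask: BinaryMask
    fraction: float = DEFAULT_FRACTION
    subregion_atlas: Mapping[str, BinaryMask] = field(default_factory=dict)
    summary: str = "mean"

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction < 1.0:
            raise ValueError(f"fraction must be in (0, 1), got {self.fraction}")
        if self.it_mask.is_empty():
            raise ValueError("inferior-temporal anchor mask is empty")
        if self.gm_mask.is_empty():
            raise ValueError("gray-matter mask is empty")
        if self.summary not in ("mean", "median"):
            raise ValueError(f"summary must be 'mean' or 'median', got {self.summary!r}")


@dataclass(frozen=True)
class MaskProvenance:
    """Audit record for a generated mask."""

    threshold: float | None
    fraction: float | None
    n_voxels: int

    def to_dict(self) -> dict:
        return {"threshold": self.threshold, "fraction": self.fraction,
                "n_voxels": self.n_voxels}


def mean_image(images: Sequence[VolumeImage]) -> VolumeImage:
    """Voxelwise mean over non-missing values.

    A voxel missing in every input is missing in the output; a voxel
    present in some inputs averages the present values only.
    """
    if len(images) < 1:
        raise ValueError("mean_image requires at least 1 image")
    grid = require_same_grid(*images)
    stack = np.stack([im.values for im in images])
    counts = (~np.isnan(stack)).sum(axis=0)
    sums = np.nansum(stack, axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return VolumeImage(grid=grid, values=mean)


def difference_image(ad_mean: VolumeImage, cu_mean: VolumeImage) -> VolumeImage:
    """AD Ab+ mean minus CU Ab- mean, voxelwise."""
    grid = require_same_grid(ad_mean, cu_mean)
    return VolumeImage(grid=grid, values=ad_mean.values - cu_mean.values)


def tracer_mask(diff: VolumeImage, cfg: MaskBuildConfig) -> tuple[BinaryMask, MaskProvenance]:
    """Threshold the difference image at fraction x its inferior-temporal summary.

    Returns the mask {voxels: diff >= tau} together with provenance
    recording tau. The comparison includes ties (>=), which is
    deterministic and measure-zero for real data. Raises if the anchor
    summary is nonpositive (no AD>CU contrast in the anchor region).
    """
    require_same_grid(diff, cfg.it_mask)
    anchor = diff.values[cfg.it_mask.membership]
    if np.isnan(anchor).all():
        raise ValueError("difference image is entirely missing over the anchor region")
    summarize = np.nanmean if cfg.summary == "mean" else np.nanmedian
    it_level = float(summarize(anchor))
    if it_level <= 0:
        raise ValueError(
            "no AD>CU contrast in anchor region: inferior-temporal "
            f"{cfg.summary} difference is {it_level:.4g}")
    tau = cfg.fraction * it_level
    with np.errstate(invalid="ignore"):
        membership = diff.values >= tau  # NaN compares False -> missing voxels excluded
    mask = BinaryMask(grid=diff.grid, membership=membership)
    return mask, MaskProvenance(threshold=tau, fraction=cfg.fraction, n_voxels=mask.n_voxels)


def universal_mask(tracer_masks: Sequence[BinaryMask], cfg: MaskBuildConfig) -> BinaryMask:
    """Intersection of tracer masks, gray-matter restricted, then mirror-fused.

    Order is fixed — intersect, GM-restrict, symmetrize — since gray-matter
    restriction and mirroring apply to the universal mask, not to the
    per-tracer masks.
    """
    if len(tracer_masks) < 2:
        raise ValueError("universal mask requires at least 2 tracer masks")
    core = intersect(list(tracer_masks) + [cfg.gm_mask])
    if core.is_empty():
        raise ValueError("universal mask is empty: tracer masks and gray matter do not overlap")
    return symmetrize(core)


def subregion_mask(universal: BinaryMask, anatomical: BinaryMask,
                   name: str = "subregion") -> BinaryMask:
    """Regional mask: universal mask intersected with an anatomical extent."""
    out = intersect([universal, anatomical])
    if out.is_empty():
        raise ValueError(f"subregion {name!r} does not intersect the universal mask")
    return out


def build_subregions(universal: BinaryMask,
                     atlas: Mapping[str, BinaryMask]) -> dict[str, BinaryMask]:
    """Carve every atlas region out of the universal mask.

    Regions may overlap (the meta-temporal composite contains the mesial
    temporal region by construction); no disjointness is assumed.
    """
    return {name: subregion_mask(universal, anat, name=name) for name, anat in atlas.items()}
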