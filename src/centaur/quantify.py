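"""SUVR computation and the CenTauR_z (CTRz) universal tau scale.

SUVR is the mean tracer uptake inside a target mask divided by the mean
uptake in the sub-cerebellar reference region. CTRz re-expresses SUVR as
a z-score against the cognitively-unimpaired amyloid-negative (CU Ab-)
population of the same tracer:

    CTRz = (SUVR - mu) / sigma = slope * SUVR + intercept

with slope = 1/sigma and intercept = -mu/sigma. Because the map is
affine, CTRz values are directly comparable across tracers: 0 is the CU
Ab- mean and each unit is one CU Ab- standard deviation of that tracer,
absorbing tracer-specific dynamic range and noise.

Published conversion coefficients for the six tracers x five regions
(SPM-pipeline SUVRs) ship as a versioned CSV data file; ``published_scales``
is its single access point. Voxelwise CTRz parametric images use the same
affine map applied to voxel/reference ratios; for a global transformation
the temporo-parietal equation is the suggested default.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .template_io import BinaryMask, VolumeImage, require_same_grid

#: Canonical region identifiers, in reporting order.
ROIS = ("universal", "mesial_temporal", "meta_temporal", "temporo_parietal", "frontal")

#: Tracers with packaged conversion equations.
TRACERS = ("RO948", "FTP", "MK6240", "GTP1", "PM-PBB3", "PI2620")

#: Suggested region for global (voxelwise) SUVR->CTRz transformation.
DEFAULT_PARAMETRIC_ROI = "temporo_parietal"


@dataclass(frozen=True)
class TracerScale:
    """One affine SUVR -> CTRz conversion for a (tracer, region) pair."""

    tracer: str
    roi: str
    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(f"slope must be positive (CTRz increases with uptake), "
                             f"got {self.slope}")

    @property
    def cu_mean(self) -> float:
        """CU Ab- mean SUVR implied by the coefficients (-intercept/slope)."""
        return -self.intercept / self.slope

    @property
    def cu_sd(self) -> float:
        """CU Ab- SUVR standard deviation implied by the coefficients (1/slope)."""
        return 1.0 / self.slope


def _masked_mean(values: np.ndarray, mask: BinaryMask) -> float:
    sel = values[mask.membership]
    if np.isnan(sel).all():
        raise ValueError("all voxels in mask are missing")
    return float(np.nanmean(sel))


def compute_suvr(pet: VolumeImage, target: BinaryMask, reference: BinaryMask) -> float:
    """Mean uptake over the target mask divided by mean over the reference mask.

    Missing voxels are excluded from both means. The ratio-of-means form
    equals the mean of voxel ratios because the reference summary is a
    single scalar divisor.
    """
    require_same_grid(pet, target, reference)
    if target.is_empty():
        raise ValueError("target mask is empty")
    if reference.is_empty():
        raise ValueError("reference mask is empty")
    ref_mean = _masked_mean(pet.values, reference)
    if ref_mean <= 0:
        raise ValueError(f"nonpositive reference mean ({ref_mean:.4g}); cannot form SUVR")
    return _masked_mean(pet.values, target) / ref_mean


def calibrate_scale(cu_suvrs: Sequence[float], tracer: str, roi: str,
                    ddof: int = 1) -> TracerScale:
    """Calibrate a CTRz scale from CU Ab- SUVRs of one tracer and region.

    slope = 1/sigma, intercept = -mu/sigma, so CTRz = (x - mu)/sigma.
    ``ddof=1`` (sample SD) by default.
    """
    x = np.asarray(cu_suvrs, dtype=float)
    if x.size < 2:
        raise ValueError(f"need at least 2 calibration SUVRs, got {x.size}")
    mu = float(np.mean(x))
    sigma = float(np.std(x, ddof=ddof))
    if sigma <= 0:
        raise ValueError("zero variance in calibration SUVRs; scale undefined")
    return TracerScale(tracer=tracer, roi=roi, slope=1.0 / sigma, intercept=-mu / sigma)


def suvr_to_ctrz(x: float | np.ndarray, scale: TracerScale) -> float | np.ndarray:
    """Apply the affine conversion CTRz = slope*x + intercept.

    Defined for any real SUVR; values below the CU Ab- mean map to
    negative CTRz (no clamping).
    """
    out = scale.slope * np.asarray(x, dtype=float) + scale.intercept
    return float(out) if np.isscalar(x) or np.ndim(x) == 0 else out


_SCALES_RESOURCE = "centaur_scales.csv"


def load_scale_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load a coefficient table (packaged published one when ``path`` is None)."""
    if path is None:
        with resources.files("centaur.data").joinpath(_SCALES_RESOURCE).open("r") as fh:
            table = pd.read_csv(fh)
    else:
        table = pd.read_csv(path)
    required = {"tracer", "roi", "slope", "intercept"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"scale table missing columns: {sorted(missing)}")
    return table


def published_scales(tracer: str | None = None, roi: str | None = None,
                     table: pd.DataFrame | None = None) -> TracerScale | dict[tuple[str, str], TracerScale]:
    """Published SUVR -> CTRz conversions (SPM pipeline), as packaged.

    With ``tracer`` and ``roi`` given, returns the single matching
    :class:`TracerScale`; otherwise a dict keyed by (tracer, roi) of all
    30 coefficient pairs.
    """
    if table is None:
        table = load_scale_table()
    scales = {(r.tracer, r.roi): TracerScale(tracer=r.tracer, roi=r.roi,
                                             slope=float(r.slope), intercept=float(r.intercept))
              for r in table.itertuples()}
    if tracer is None and roi is None:
        return scales
    known_tracers = sorted({t for t, _ in scales})
    known_rois = sorted({r for _, r in scales})
    if tracer not in known_tracers:
        raise KeyError(f"unknown tracer {tracer!r}; known: {known_tracers}")
    if roi not in known_rois:
        raise KeyError(f"unknown ROI {roi!r}; known: {known_rois}")
    return scales[(tracer, roi)]


def ctrz_image(pet: VolumeImage, reference: BinaryMask,
               scale: TracerScale | None = None, tracer: str | None = None) -> VolumeImage:
    """Voxelwise CTRz parametric image.

    Every voxel is divided by the reference-region mean (a scalar) and
    passed through the affine conversion. When ``scale`` is omitted the
    tracer's published temporo-parietal equation is used, the suggested
    choice for global transformations.
    """
    if scale is None:
        if tracer is None:
            raise ValueError("either a scale or a tracer must be given")
        scale = published_scales(tracer=tracer, roi=DEFAULT_PARAMETRIC_ROI)
    require_same_grid(pet, reference)
    if reference.is_empty():
        raise ValueError("reference mask is empty")
    ref_mean = _masked_mean(pet.values, reference)
    if ref_mean <= 0:
        raise ValueError(f"nonpositive reference mean ({ref_mean:.4g})")
    values = scale.slope * (pet.values / ref_mean) + scale.intercept
    return VolumeImage(grid=pet.grid, values=values)
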