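"""Synthetic template-space phantoms and cohorts with known ground truth.

The phantom emulates what the quantification framework actually consumes:
spatially normalized static tau-PET volumes with a cerebellar reference
slab, a gray-matter envelope, and mirror-symmetric cortical regions whose
uptake is controlled per subject. Subjects are generated as

    image = reference_level * (1 outside regions, region SUVR inside)
            + Gaussian noise, optionally Gaussian-smoothed

so the noiseless region SUVR equals the drawn value exactly by
construction. Region SUVRs are drawn Normal(cu_mean, cu_sd) per subject,
with an additive disease effect in the regions dictated by the
topographic subtype (limbic-predominant elevates the mesial temporal
region only, hippocampal-sparing the cortical regions only, typical
both, tau-negative none).

Noise is additive Gaussian in uptake units: real PET noise is more
structured, but the framework's arithmetic is contrast- and scale-based
and needs only controllable first and second moments. All randomness
flows through one explicit numpy Generator.

Default condition values: reference_level 1.0 (arbitrary uptake units);
CU SUVR mean 1.1 and SD 0.1 per region, comparable to the CU Ab-
moments implied by the published MK6240 conversions; disease effect 1.0
SUVR, placing the AD meta-temporal CTRz near 10, inside the published
AD cohort range (8.1-22); per-voxel noise SD 0.05 uptake units;
smoothing off by default so unit checks stay exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .classify import SubtypeLabel
from .mask_ops import ReferenceRegionSpec, build_reference_region, union
from .quantify import calibrate_scale, compute_suvr, suvr_to_ctrz
from .template_io import BinaryMask, TemplateGrid, VolumeImage, default_grid

#: Cortical regions painted by the generator (all inside gray matter,
#: disjoint from each other and from the cerebellum).
CORTICAL_REGIONS = ("mesial_temporal", "inferior_temporal", "meta_temporal",
                    "temporo_parietal", "frontal")

#: Regions elevated by each topographic subtype.
SUBTYPE_ELEVATED: dict[SubtypeLabel, frozenset[str]] = {
    SubtypeLabel.TAU_NEGATIVE: frozenset(),
    SubtypeLabel.LIMBIC_PREDOMINANT: frozenset({"mesial_temporal"}),
    SubtypeLabel.HIPPOCAMPAL_SPARING: frozenset(
        {"inferior_temporal", "meta_temporal", "temporo_parietal", "frontal"}),
    SubtypeLabel.TYPICAL: frozenset(CORTICAL_REGIONS),
}


def _per_region(value: float | Mapping[str, float], default: float) -> dict[str, float]:
    if isinstance(value, Mapping):
        out = {r: float(value.get(r, default)) for r in CORTICAL_REGIONS}
    else:
        out = {r: float(value) for r in CORTICAL_REGIONS}
    return out


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for the phantom cohort generator."""

    grid: TemplateGrid = field(default_factory=lambda: default_grid((32, 38, 32), 4.0))
    reference_level: float = 1.0
    cu_suvr_mean: float | Mapping[str, float] = 1.1
    cu_suvr_sd: float | Mapping[str, float] = 0.1
    ad_effect: float | Mapping[str, float] = 1.0
    noise_sd: float = 0.05
    smoothing_fwhm: float = 0.0
    tracer: str = "PHANTOM"

    def __post_init__(self) -> None:
        if self.reference_level <= 0:
            raise ValueError("reference_level must be positive")
        if self.noise_sd < 0 or self.smoothing_fwhm < 0:
            raise ValueError("noise_sd and smoothing_fwhm must be nonnegative")
        means = _per_region(self.cu_suvr_mean, 1.1)
        sds = _per_region(self.cu_suvr_sd, 0.1)
        effects = _per_region(self.ad_effect, 1.0)
        if any(s < 0 for s in sds.values()):
            raise ValueError("cu_suvr_sd must be nonnegative")
        object.__setattr__(self, "_means", means)
        object.__setattr__(self, "_sds", sds)
        object.__setattr__(self, "_effects", effects)

    @property
    def region_means(self) -> dict[str, float]:
        return dict(self._means)

    @property
    def region_sds(self) -> dict[str, float]:
        return dict(self._sds)

    @property
    def region_effects(self) -> dict[str, float]:
        return dict(self._effects)


@dataclass(frozen=True)
class SimulatedSubject:
    """One phantom scan with its generating truth."""

    image: VolumeImage
    group: str
    abeta: str
    subtype: SubtypeLabel
    true_suvr: dict[str, float]


def _world_box(grid: TemplateGrid, x=(-np.inf, np.inf), y=(-np.inf, np.inf),
               z=(-np.inf, np.inf), abs_x: tuple[float, float] | None = None) -> BinaryMask:
    wx, wy, wz = grid.world_coords()
    sel = (wy >= y[0]) & (wy <= y[1]) & (wz >= z[0]) & (wz <= z[1])
    if abs_x is not None:
        sel &= (np.abs(wx) >= abs_x[0]) & (np.abs(wx) <= abs_x[1])
    else:
        sel &= (wx >= x[0]) & (wx <= x[1])
    return BinaryMask(grid=grid, membership=sel)


def make_layout(spec: PhantomSpec) -> dict[str, BinaryMask]:
    """Deterministic mirror-symmetric region layout on the spec's grid.

    All region extents are world-mm boxes symmetric about x = 0: an
    inferior cerebellar slab spanning z below -30 mm (so the -47..-37 mm
    reference slab is nonempty), a gray-matter envelope above it, and
    five disjoint cortical boxes inside gray matter. Raises if the grid
    is too small to make every region nonempty.
    """
    g = spec.grid
    layout = {
        "cerebellar_cortex": _world_box(g, abs_x=(0, 24), y=(-40, 16), z=(-54, -30)),
        "gray_matter": _world_box(g, abs_x=(0, 48), y=(-60, 60), z=(-14, 50)),
        "mesial_temporal": _world_box(g, abs_x=(0, 16), y=(-18, 18), z=(-14, -4)),
        "inferior_temporal": _world_box(g, abs_x=(24, 48), y=(-18, 18), z=(-14, -4)),
        "meta_temporal": _world_box(g, abs_x=(24, 48), y=(-34, 34), z=(0, 14)),
        "temporo_parietal": _world_box(g, abs_x=(0, 32), y=(-52, -24), z=(18, 38)),
        "frontal": _world_box(g, abs_x=(0, 32), y=(24, 52), z=(18, 38)),
    }
    for name, mask in layout.items():
        if mask.is_empty():
            raise ValueError(f"grid too small: phantom region {name!r} is empty")
    return layout


def simulate_subject(spec: PhantomSpec, group: str, subtype: SubtypeLabel,
                     rng: np.random.Generator,
                     layout: Mapping[str, BinaryMask] | None = None) -> SimulatedSubject:
    """Draw one phantom scan for a diagnostic group and topographic subtype."""
    if layout is None:
        layout = make_layout(spec)
    elevated = SUBTYPE_ELEVATED[subtype]
    values = np.full(spec.grid.shape, spec.reference_level, dtype=float)
    true_suvr: dict[str, float] = {}
    for region in CORTICAL_REGIONS:
        suvr = rng.normal(spec.region_means[region], spec.region_sds[region])
        if region in elevated:
            suvr += spec.region_effects[region]
        values[layout[region].membership] = spec.reference_level * suvr
        true_suvr[region] = float(suvr)
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=spec.grid.shape)
    if spec.smoothing_fwhm > 0:
        sigma_mm = spec.smoothing_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        sigma_vox = [sigma_mm / v for v in spec.grid.voxel_size]
        values = gaussian_filter(values, sigma=sigma_vox)
    abeta = "pos" if group == "AD" else "neg"
    return SimulatedSubject(image=VolumeImage(grid=spec.grid, values=values),
                            group=group, abeta=abeta, subtype=subtype,
                            true_suvr=true_suvr)


#: Measurement ROIs reported in the cohort table, in column order.
MEASURED_ROIS = ("universal",) + CORTICAL_REGIONS


def simulate_cohort(spec: PhantomSpec, n_cu: int, n_ad: int,
                    seed: int | np.random.Generator | None = None,
                    ad_subtype: SubtypeLabel = SubtypeLabel.TYPICAL,
                    ) -> tuple[list[SimulatedSubject], pd.DataFrame]:
    """Simulate a CU Ab- / AD Ab+ cohort and quantify it end to end.

    Returns the subjects plus a cohort table with measured SUVR per ROI,
    CTRz computed against a scale calibrated on this cohort's CU Ab-
    subjects, and the generating truth. The ``universal`` ROI is the
    union of the cortical regions.
    """
    if n_cu < 2:
        raise ValueError("need n_cu >= 2 to calibrate the CTRz scale")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    layout = make_layout(spec)
    reference = build_reference_region(ReferenceRegionSpec(base_mask=layout["cerebellar_cortex"]))
    roi_masks: dict[str, BinaryMask] = {r: layout[r] for r in CORTICAL_REGIONS}
    roi_masks["universal"] = union([layout[r] for r in CORTICAL_REGIONS])

    subjects: list[SimulatedSubject] = []
    rows: list[dict] = []
    for i in range(n_cu + n_ad):
        is_cu = i < n_cu
        subj = simulate_subject(
            spec, group="CU" if is_cu else "AD",
            subtype=SubtypeLabel.TAU_NEGATIVE if is_cu else ad_subtype,
            rng=rng, layout=layout)
        subjects.append(subj)
        row = {"subject_id": f"sub-{i:04d}", "tracer": spec.tracer,
               "group": subj.group, "abeta": subj.abeta,
               "subtype_true": subj.subtype.value}
        for roi, mask in roi_masks.items():
            row[f"suvr_{roi}"] = compute_suvr(subj.image, mask, reference)
        counts = {r: layout[r].n_voxels for r in CORTICAL_REGIONS}
        total = sum(counts.values())
        for roi in CORTICAL_REGIONS:
            row[f"true_suvr_{roi}"] = subj.true_suvr[roi]
        row["true_suvr_universal"] = sum(
            subj.true_suvr[r] * counts[r] for r in CORTICAL_REGIONS) / total
        rows.append(row)

    table = pd.DataFrame(rows)
    cu = table[table["group"] == "CU"]
    for roi in MEASURED_ROIS:
        scale = calibrate_scale(cu[f"suvr_{roi}"].to_numpy(), tracer=spec.tracer, roi=roi)
        table[f"ctrz_{roi}"] = suvr_to_ctrz(table[f"suvr_{roi}"].to_numpy(), scale)
    return subjects, table
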