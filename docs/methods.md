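# Methods

## Scope and model

The package is a pure quantification layer for tau-PET volumes that are
already spatially normalized to a common template. It never resamples:
every multi-image operation first checks that shapes match and affines
agree elementwise within 1e-3 mm, and fails otherwise. Grid geometry is
data (read from each NIfTI header), not an assumption; the conventional
91×109×91, 2 mm normalized-space grid is only a convenience default for
constructing grids in code.

Missing voxels are represented as NaN, excluded from every mean and
from mask membership, and counted in a logged warning at load time.
Only single static (3-D) frames are accepted; dynamic series are
rejected rather than silently averaged.

### Reference region

The SUVR reference is the cerebellar-cortex mask restricted to an axial
slab of template-space world z, by default −47 mm ≤ z ≤ −37 mm. The
upper cut avoids vermis off-target binding; the lower cut avoids
partial-volume and out-of-field effects at the cerebellar edge. The
bounds are interpreted as **world z in mm** (not slice indices), since
cerebellar extent in Centiloid-style template space is conventionally
expressed in MNI-style mm coordinates, and they are **inclusive**:
the exclusions are strict (`z > −37`, `z < −47`), so the kept slab is
the closed interval. Both bounds are configurable in case a
distributed mask uses a different convention.

### Mask generation

Per tracer: mean CU Aβ− image, mean AD Aβ+ image, difference
(AD − CU), threshold at `fraction × summary(difference over the
inferior-temporal anchor mask)` with `fraction = 1/3` and
`summary = mean` by default. The anchor summary statistic is a design
choice — mean is the standard summary; median is available by
configuration. Threshold comparison is `>=` (ties included), which is
deterministic and measure-zero on real data. A nonpositive anchor
contrast is an error: it means the cohorts show no AD>CU signal where
tau is expected.

The universal mask is `symmetrize(intersect(tracer_masks) ∩ GM)`, in
that fixed order: gray-matter restriction and mirroring apply to the
universal mask, not per tracer. Probabilistic gray-matter maps are
binarized at > 0.5. "Mirror-fusing" is the **union** of the mask with
its reflection across the world x = 0 plane — union is the monotone
choice that removes hemispheric asymmetry without discarding observed
topography. Reflection requires a voxel axis aligned with world x
(within 1e-6); the reflected index is the nearest voxel to the exact
mirror position, which makes the map an involution, so symmetrization
is idempotent and its output exactly mirror-invariant even when the
midplane bisects a voxel column.

Regional masks are intersections of the universal mask with anatomical
extents supplied as data (the anatomical geometry is an atlas input,
not code). Regions may overlap — the meta-temporal composite contains
the mesial temporal region by construction — so no disjointness is
assumed or asserted.

### SUVR and the CTRz scale

Region SUVR is mean uptake over the target mask divided by mean uptake
over the reference mask (missing voxels excluded). Because the
reference summary is a single scalar, ratio-of-means and
mean-of-voxel-ratios coincide; the ratio-of-means form is the
documented one to prevent drift.

CTRz is the affine map `CTRz = slope·SUVR + intercept` with
`slope = 1/σ`, `intercept = −μ/σ`, where μ and σ are the mean and
**sample (n−1)** standard deviation of the CU Aβ− calibration SUVRs —
sample SD is the standard choice for cohort z-scores and is
configurable (`ddof`). CTRz is defined for all real SUVR; values below
the CU mean are meaningfully negative and are not clamped. The
published coefficients (six tracers × five regions, SPM-pipeline
SUVRs) ship as `src/centaur/data/centaur_scales.csv` with signed
intercepts; that file is the single source of truth, and alternative
coefficient tables (e.g. for a different processing pipeline) can be
loaded through the same schema via its `pipeline` column.

Parametric images apply the same affine map to every voxel divided by
the scalar reference mean. When no explicit scale is given, the
tracer's temporo-parietal equation is used — the suggested choice for
a global voxelwise transformation. The ROI mean of a parametric image
equals the scalar SUVR→CTRz pathway to floating-point precision (an
algebraic identity the tests check at 1e-9).

### Classification

Positivity is strictly `CTRz > threshold` (default 2). A value exactly
at the threshold counts negative everywhere: the boundary is
measure-zero and assigning it to negative keeps every rule
deterministic. Topographic subtypes form the exhaustive 2×2 partition
on (mesial-temporal positive, meta-temporal positive):
negative/negative → tau-negative, positive/negative →
limbic-predominant, negative/positive → hippocampal-sparing,
positive/positive → typical. The hippocampal-sparing cell is the
completion of the 2×2 logic from the explicitly stated tau-negative
and limbic-predominant rules. Diagnostic metrics are the usual
confusion-matrix proportions; sensitivity and specificity are refused
(not silently NaN) when the truth vector lacks positives or negatives.
No threshold optimization is performed; the operating point is fixed a
priori.

## Phantom cohorts

The generator emulates exactly what the quantification layer consumes.
The default grid is 32×38×32 at 4 mm (a scaled-down template), with
world origin at the grid center. The layout is a set of world-mm boxes,
all symmetric about x = 0: an inferior cerebellar slab spanning
z ∈ [−54, −30] mm (so the reference slab is nonempty), a gray-matter
envelope at z ≥ −14 mm, and five disjoint cortical boxes (mesial
temporal, inferior temporal, meta temporal, temporo-parietal, frontal)
inside gray matter.

Each subject's image is `reference_level` everywhere except inside the
cortical regions, where it is `reference_level × SUVR_r` with
`SUVR_r ~ Normal(cu_mean, cu_sd)` per region, plus a disease effect in
the regions dictated by the topographic subtype (limbic-predominant:
mesial only; hippocampal-sparing: cortical only; typical: both;
tau-negative: none). Additive Gaussian voxel noise and optional
isotropic Gaussian smoothing (FWHM in mm, emulating PET resolution)
follow. The noiseless region SUVR therefore equals the drawn value
exactly, which is what makes closure tests exact. All randomness flows
through one explicit numpy `Generator`; there is no global state.

Default conditions: reference level 1.0 (arbitrary uptake units); CU
SUVR mean 1.1 and SD 0.1 per region — comparable to the CU Aβ− moments
implied by the packaged MK6240 conversions (μ = −intercept/slope ≈ 1.13,
σ = 1/slope ≈ 0.107 in the meta-temporal region); disease effect 1.0
SUVR, which places the AD meta-temporal CTRz near 10, inside the
published AD cohort range of 8.1–22; per-voxel noise SD 0.05;
smoothing off (unit checks stay exact). Cohort tables are quantified
end-to-end: measured SUVR per region plus a `universal` union region,
CTRz calibrated on the cohort's own CU Aβ− subjects, and the
generating truth retained. Exclusion logic (QC failures and the like)
is the caller's responsibility, not the calibration routine's.

What the phantom does **not** emulate: real anatomy, off-target
binding (choroid plexus, meninges, vermis hot spots), scanner PSFs,
spatially correlated or count-dependent PET noise, and registration
error. Passing tests therefore demonstrate that the arithmetic of the
framework — masks, ratios, affine scales, thresholds — is correct
under controlled first and second moments, not that the published
cohort-specific accuracies, Dice scores or prevalences would be
reproduced on real scans; those depend on the six source cohorts.

## Test problem sizes and numerical choices

Mask-pipeline recovery is checked exactly on noiseless phantoms (3
subjects per group) and stochastically at a per-voxel
contrast-to-noise ratio of 5 in the difference image (16 subjects per
group, two simulated tracers, ten seeds, Dice ≥ 0.9). Calibration
recovery uses n = 200 CU draws with a 1000-replicate bootstrap SE and
a 500-replicate bias sweep (the 1/s estimator's small-sample bias is
≈ 3/(4n) ≈ 0.4 % at n = 200, well under the 2 % band). The
classification operating point is checked on 100 + 100 subjects.
These sizes are chosen so the full suite runs in seconds while keeping
every stochastic margin wide.

Tolerances: affine round-trips are exact (scale calibration inverts to
1e-12; parametric-image identities to 1e-9); grid compatibility is
1e-3 mm elementwise on affines; mirror-axis detection is 1e-6.

## Known limitations

- No partial-volume correction, motion correction or frame averaging.
- No morphological cleanup of generated masks (no opening/closing or
  cluster-size filtering) — none is part of the procedure.
- The packaged anatomical subregion extents exist only for the phantom
  layout; applying the framework to real data requires the distributed
  template-space masks (or any atlas on the scan grid) as inputs.
- Longitudinal reproducibility is untested by design; the framework
  quantifies single time points.
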