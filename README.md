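# centaur

Standardized tau-PET quantification on a universal scale.

Tau PET tracers (¹⁸F-flortaucipir, ¹⁸F-MK6240, ¹⁸F-PI2620, ¹⁸F-PM-PBB3,
¹⁸F-GTP1, ¹⁸F-RO948) differ in binding affinity, kinetics and off-target
signal, so standardized uptake value ratios (SUVR) are not comparable
across tracers or sites. This package implements a harmonization
framework for template-space tau scans:

- **Tau mask construction** from group-mean images: average cognitively
  unimpaired amyloid-negative (CU Aβ−) and AD amyloid-positive (AD Aβ+)
  scans per tracer, subtract, threshold the difference image at one
  third of its mean over an inferior-temporal anchor region, intersect
  the tracer-specific masks into a *universal* tau mask, restrict to
  gray matter, and mirror-fuse across the sagittal midplane to remove
  hemispheric asymmetry. Regional masks (mesial temporal, meta temporal,
  temporo-parietal, frontal) are carved from the universal mask with an
  anatomical atlas. Mask agreement is measured with the Dice index
  2|A∩B|/(|A|+|B|).
- **SUVR** against a sub-cerebellar reference region: the cerebellar
  cortex mask restricted to template-space slices −47 mm ≤ z ≤ −37 mm,
  avoiding vermis off-target binding above and edge artifacts below.
- **The CenTauR_z (CTRz) scale**: per tracer and region, CTRz =
  (SUVR − μ)/σ where μ, σ are the mean and SD of the CU Aβ− calibration
  group — equivalently CTRz = a·SUVR + b with a = 1/σ, b = −μ/σ. The
  published coefficients for all six tracers × five regions ship as a
  packaged data table. The same affine map applied voxelwise (the
  temporo-parietal equation is the suggested global choice) yields CTRz
  parametric images.
- **Classification**: tau positivity is CTRz > 2 in a region (the
  meta-temporal region is the headline discriminator), and the 2×2 rule
  on mesial- vs meta-temporal positivity assigns the topographic
  subtypes tau-negative / limbic-predominant / hippocampal-sparing /
  typical.
- **Phantom cohorts**: a synthetic-data module generates template-grid
  region layouts and CU/AD cohorts with known ground truth, so the whole
  pipeline is testable with no image downloads.

Spatial normalization is out of scope: all inputs must already share a
template grid, and nothing is ever resampled silently.

## Worked example

```python
from centaur import (PhantomSpec, simulate_cohort, diagnostic_metrics,
                     published_scales, suvr_to_ctrz)

scale = published_scales(tracer="MK6240", roi="meta_temporal")
print(f"MK6240 meta-temporal: CTRz = {scale.slope:.2f} * SUVR {scale.intercept:+.2f}")
print(f"SUVR 1.8 -> CTRz {suvr_to_ctrz(1.8, scale):.2f}")

subjects, table = simulate_cohort(PhantomSpec(), n_cu=100, n_ad=100, seed=7)
print(table.groupby("group")["ctrz_meta_temporal"].agg(["mean", "std"]).round(2))
m = diagnostic_metrics((table.ctrz_meta_temporal > 2).tolist(),
                       (table.group == "AD").tolist())
print(f"accuracy={m.accuracy:.2f} sensitivity={m.sensitivity:.2f} "
      f"specificity={m.specificity:.2f}")
```

prints

```
MK6240 meta-temporal: CTRz = 9.36 * SUVR -10.60
SUVR 1.8 -> CTRz 6.25
        mean   std
group
AD     10.28  0.95
CU     -0.00  1.00
accuracy=0.99 sensitivity=1.00 specificity=0.98
```

The conversion line is the published MK6240 meta-temporal equation; an
SUVR of 1.8 sits 6.25 CU-standard-deviations above the CU Aβ− mean. The
simulated CU group has meta-temporal CTRz of exactly mean 0, SD 1 by
construction (the scale is calibrated on it), the AD group lands near
CTRz 10 — inside the published AD cohort range of 8.1–22 — and the
CTRz > 2 operating point separates the groups almost perfectly.

## Command-line interface

`centaur` exposes the library as thin subcommands:
`dice`, `refregion`, `build-mask`, `build-universal`, `subregions`,
`quantify`, `calibrate`, `parametric`, `classify`, `metrics`,
`simulate`. Volumes and masks are NIfTI-1 (`.nii`/`.nii.gz`) on a shared
grid; cohort tables are CSV. For example:

```sh
centaur simulate --n-cu 100 --n-ad 100 --seed 7 --out sim/
centaur classify --table sim/cohort.csv --out sim/classified.csv
centaur metrics --table sim/classified.csv
```

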