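# gliomorph

Tumor size/shape morphometry from 3D segmentation masks, plus the
prognostic survival-analysis plan those measurements feed into.

From a binary tumor mask (NIfTI, anisotropic spacing supported) the
package computes:

- **volume** (mL) — voxel count × voxel volume;
- **TSA** (cm²) — total surface area of the triangulated isosurface,
  with feature-aware clamped Taubin smoothing to remove the voxelization
  staircase (no vertex moves more than half a voxel);
- **CSA** (cm²) — TSA minus the dura-adjacent portion, localized
  automatically against a brain mask (distance + normal-direction gate)
  or from user-supplied per-voxel contact labels;
- **SI** — sphericity index, TSA over the area of the equal-volume sphere;
- **A/V** (cm⁻¹) — area-to-volume ratio;
- **EOR** (%) — extent of resection from pre/post volumes, with the
  GTR/STR dichotomy.

The analysis stage mirrors the published plan: Shapiro–Wilk screen,
Mann–Whitney/Kruskal–Wallis group tests, Spearman correlations,
univariable Cox models per measure, two fixed multivariable Cox models
(CSA-based and SI-based; Efron or Breslow ties) with the postoperative
KPS hazard split at day 300 via counting-process episodes, scaled
Schoenfeld proportionality checks, Kaplan–Meier curves with log-rank
tests, and Harrell C-index / AIC model comparison.

Because the motivating patient data are access-restricted, the package
ships two synthetic generators that make every stage testable:

- `synthetic_shapes` — digitized balls, cubes, ellipsoids, harmonically
  perturbed "bumpy" balls and plane-truncated balls with closed-form
  volume/area/contact references;
- `synthetic_cohort` — patient tables matching the published marginal
  summaries, with survival drawn from a Weibull proportional-hazards
  model at user-chosen hazard ratios (including a switch that makes the
  KPS effect decay after day 300, for step-function experiments).

## CLI

```bash
# synthetic tumor + brain-context masks with analytic reference sidecar
gliomorph simulate-shape --kind bumpy_ball --radius-mm 20 --amplitude 0.3 \
    --degree 6 --seed 7 -o tumor.nii.gz

# morphometry for one case
gliomorph measure --pre tumor.nii.gz --brain brain.nii.gz \
    --contact-tolerance-mm 1.0 -o morphometry.csv

# synthetic cohort and full statistical report
gliomorph simulate-cohort --n 271 --seed 11 -o cohort.csv
gliomorph analyze --cohort cohort.csv -o report/

# full pipeline (measure -> merge covariates -> analyze) from YAML
gliomorph run --config pipeline.yaml
```

A pipeline config lists cases (`case_id`, `pre`, optional `post`,
`brain`, `contact`) plus options (`contact_tolerance_mm`, `connectivity`,
`split_day`, `ties`, `seed`, `covariates_csv`, `output_dir`). Every run
writes `config.resolved.json`, a per-case `morphometry.csv` and an
`exclusions.csv` logging multifocal/empty/unreadable cases with reasons.

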