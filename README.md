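# vrsquant

Automated quantification of **Virchow–Robin spaces** (VRs, also called
perivascular spaces) on axial T2-weighted MRI, together with the cohort
statistics used to relate VRs burden to simple febrile seizure (SFS)
severity in young children — and synthetic phantoms/cohorts so that every
stage is testable without any clinical data.

Enlarged VRs are CSF-filled channels around perforating vessels and are
used as an imaging proxy for glymphatic (perivascular fluid-exchange)
dysfunction. On T2-weighted images they appear as small bright linear or
circular structures in the white matter. This package reimplements, as a
tested reusable pipeline, an automated approach to counting and measuring
them in the supraventricular white matter, and the group-level analysis
that compares children with long (> 5 min) seizures, short (≤ 5 min)
seizures, and controls.

## What the pipeline does

Per subject (`vrsquant.run_subject_pipeline`):

1. **Brain extraction** — Otsu threshold, largest 3D component, per-slice
   hole filling.
2. **Tissue segmentation** — 1-D k-means (k = 3) on intensities inside the
   brain mask; classes named WM < GM < CSF by the T2 ordering.
3. **Ventricle localisation** — central, large CSF components; their top
   slice `z_v` anchors the counting region.
4. **Supraventricular ROI** — hole-filled WM on slices `z ≥ z_v` (enclosed
   CSF-bright voxels are retained: visible VRs must not be excluded by
   their own signal), minus a small dilated ventricle rim.
5. **Multi-scale 2D Frangi vesselness** per axial slice, from the
   eigenvalues `|λ₁| ≤ |λ₂|` of the scale-normalised Hessian:

   ```
   V = 0                                              if λ₂ ≥ 0
   V = exp(−R_B²/2β²) · (1 − exp(−S²/2c²))            otherwise
   R_B = λ₁/λ₂ (blobness),  S = √(λ₁²+λ₂²) (structureness)
   ```

   Scales are physical ({0.375, 0.75, 1.125, 1.5} mm by default), β = 0.5,
   and `c` adapts per slice and scale to half the maximum Hessian norm.
6. **Quantification** — threshold (default V ≥ 0.20) inside the ROI,
   3D 26-connected components, minimum size 2 voxels, yielding the four
   per-subject metrics: **VRs count, VRs volume (mm³), WM volume, brain
   volume**.

Cohort level (`vrsquant.stats`): pairwise Mann–Whitney U tests at the
Bonferroni-adjusted level α/3 = .017, Pearson correlations of VRs metrics
with seizure duration and with the course from seizure onset to the scan,
and a LOESS-based changepoint detector for the seizure-duration cutoff.

Synthetic data (`vrsquant.synthetic`): MR-like phantoms (ellipsoidal
brain, GM shell, paramedian ventricles, embedded tubular VRs with exact
voxel ground truth, Rician noise) and cohort tables drawn from a Gaussian
copula with truncated-normal margins matched to the published group
means ± SDs and within-group correlations.

## Worked example

```bash
$ vrsquant simulate-phantom --out phantom --seed 11 --n-structures 25
phantom with 25 structures -> phantom

$ vrsquant quantify --in phantom/phantom.nii.gz --out metrics.csv
count=25 volume=2400.8mm3 -> metrics.csv
```

The phantom had 25 embedded structures totalling 2 216.25 mm³ of
rasterised tube volume (recorded in `phantom/manifest.json`); the pipeline
recovers all 25 and measures 2 400.8 mm³ (the
metrics CSV also carries the WM and brain volumes and a parameter hash so
the numbers are reproducible).

```bash
$ vrsquant simulate-cohort --out cohort.csv --seed 3
105 subjects -> cohort.csv

$ vrsquant stats --cohort cohort.csv --out reports
vrsquant 0.1.0 cohort report
groups: SFS>5M (n=30), SFS<=5M (n=40), control (n=35)
duration cutoff 4.17 min (max_abs_curvature, span 0.5)

pairwise comparisons (Mann-Whitney U, Bonferroni-adjusted alpha .017):
  vrs_count          SFS>5M vs SFS<=5M      p=<.001 *
  vrs_count          SFS>5M vs control      p=<.001 *
  vrs_count          SFS<=5M vs control     p=.058
  vrs_volume_mm3     SFS>5M vs SFS<=5M      p=<.001 *
  vrs_volume_mm3     SFS>5M vs control      p=<.001 *
  vrs_volume_mm3     SFS<=5M vs control     p=.099
  wm_volume_mm3      SFS>5M vs SFS<=5M      p=.976
  ...
```

Children with long seizures carry significantly more and larger VRs than
both other groups, while WM volume, head circumference and brain volume do
not differ — the expected pattern under the synthetic cohort's group
parameters. `reports/` holds the summary, comparison, correlation and
cutoff tables as CSV plus the plain-text report.

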