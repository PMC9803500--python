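# Methods

This note documents the models, parameters and design choices behind
`vrsquant`: what the synthetic data emulate, how each pipeline stage is
defined, the numerical conventions, and what the tests do and do not
establish about behaviour on real clinical scans.

## 1. Image phantoms

The phantom emulates the T2-weighted contrast the pipeline consumes, not
anatomy. It is an ellipsoidal "brain" (semi-axes 0.45/0.45/0.46 of the
grid) on a zero background, with a GM shell outside normalised radius
0.88, a WM interior, and two paramedian ellipsoidal ventricles whose
rasterised top slice equals the configured `ventricle_top_slice`
(default 12). Default tissue means are WM 100, GM 130, CSF 200 on an
arbitrary T2-like scale (CSF > GM > WM is enforced), with zero tissue
texture before noise.

The default grid is 160 × 160 × 24 voxels at 0.75 × 0.75 × 4 mm — the
acquisition-style spacing (240 mm field of view on a 320 × 320 matrix,
4 mm slices without gap) kept exactly, with the in-plane field of view
halved so desk-scale tests run in seconds. `PhantomConfig.full_resolution()`
restores the 320 × 320 grid. Voxel volume at this geometry is 2.25 mm³,
and all reported volumes are voxel counts times that constant.

**VRs structures** are cylinders rasterised by an exact
voxel-centre-in-cylinder test, painted at CSF intensity, in two
orientations: *linear* (axis in the slice plane; a bright line on one
slice, since the 0.75 mm tube radius is far below the 4 mm slice
thickness) and *circular* (axis through-plane; a bright dot/disk on
consecutive slices). Ground truth records the per-structure label map,
tissue map, ventricle mask and exact count/volume; true volume is by
construction the labelled voxel count times the voxel volume.

The random structure placer draws, per structure, kind (40 % circular),
radius (linear 1.0–1.5 mm, circular 1.75–2.5 mm), length (linear
6–12 mm, circular 8–16 mm) and position, under three constraints: all
voxels inside WM at least 3 voxels clear of the GM boundary (a VRs must
remain an *enclosed* hole of its WM slice, or the ROI's hole-filling
cannot reclaim it), a 3-voxel in-plane plus 1-slice 3D margin around the
ventricles (a CSF structure touching the ventricle roof would merge with
it under 26-connectivity and corrupt the detected ventricular level), and
a 4.5 mm surface-to-surface gap between structures so that components
remain resolvable. The radii represent *visibly enlarged* perivascular
spaces; dots at the 0.75 mm resolution limit rasterise to 1–4 voxels and
cannot be rendered or measured meaningfully on this grid, so the circular
population is drawn wider than the linear one.

**Noise** is Rician: each voxel v becomes √((v+n₁)² + n₂²) with n₁, n₂
zero-mean Gaussians of SD σ (default 5, i.e. SNR 20 in WM). σ = 0 returns
the input unchanged. The closed-form checks in the tests (Rayleigh mean
σ√(π/2) at zero signal; Gaussian SD at high SNR) pin the model down.

## 2. Preprocessing

*Brain extraction* — Otsu threshold over the volume, largest 26-connected
component, per-slice hole filling. *Tissue segmentation* — k-means
(k = 3, 10 restarts, seed-controlled) on the 1-D intensity distribution
inside the mask; above 100 k voxels the centres are fitted on a
deterministic subsample and all voxels assigned to the nearest centre.
Classes are named WM/GM/CSF by ascending mean, which is the T2 ordering.
These simple stand-ins are adequate for phantoms; they are not expected
to survive bias fields, coil shading or motion on clinical data.

*Ventricles* — CSF components (3D, 26-connectivity) with volume
> 500 mm³ and in-plane centroid in the central third of the field; `z_v`
is the top slice of the combined mask. *Supraventricular ROI* — per slice
z ≥ z_v ("at and above the ventricular level", the inclusive reading),
the WM mask with in-plane holes filled — deliberately keeping
CSF-intensity voxels enclosed by WM, which is exactly where visible VRs
live — minus the ventricle mask dilated in-plane by 2 voxels. The
dilation suppresses partial-volume rims along the ventricle boundary,
which otherwise seed spurious 2–3-voxel tubular responses on the
boundary slice.

## 3. Vesselness

Strictly two-dimensional filtering per axial slice: at 4 mm slice
thickness, through-plane second derivatives are meaningless, so the
operator uses the 2-eigenvalue form (no λ₃ terms). For each scale σ the
Hessian is computed by separable Gaussian-derivative convolution and
multiplied by σ² for cross-scale comparability; σ is specified in mm and
converted to pixels via the in-plane spacing, making responses
resolution-independent.

The derivative kernels are sampled Gaussians with two moment
corrections: the zeroth moment of the first/second-derivative kernels is
projected out (a constant image yields exactly zero) and the defining
moment is rescaled (the second derivative of x² is exactly 2). Raw
sampled kernels leak ≈ 1e−4 relative on constants — harmless in absolute
terms but fatal under a data-adaptive normalisation, which happily
amplifies a featureless slice's numerical noise into a uniform 0.12
response — and are biased by ≈ 4 % on quadratics at σ = 2 px. A response
floor (Hessian norm below 1e−10 of the image scale ⇒ zero) makes
"featureless slice ⇒ V ≡ 0" exact.

Eigenvalues come from the closed 2 × 2 symmetric form, ordered
|λ₁| ≤ |λ₂| with exact-magnitude ties broken as λ₁ ≥ λ₂; λ₂ = 0 defines
R_B = 0 (the structureness factor vanishes there anyway, so no division
by zero can contribute). β defaults to 0.5; `c` defaults, per slice and
per scale, to half the maximum Hessian Frobenius norm, with a fixed
override in the configuration. The multi-scale response is the per-pixel
maximum over {0.375, 0.75, 1.125, 1.5} mm, recording the winning scale.
None of β, c, the scale set or the downstream threshold are published
values; all are reconstruction defaults, are configurable, and are
recorded in every run's provenance.

## 4. Quantification

Binarise V ≥ 0.20 inside the ROI; label connected components; drop
components below 2 voxels; count and measure. The default connectivity
is 3D 26-connected, so one anatomical structure crossing slices counts
once; per-slice 2D counting (8-connectivity) is available behind
`connectivity="2d8"` because the upstream filtering is two-dimensional
and either reading of a "count" is defensible. All parameters, plus a
hash over them, travel with the metrics.

On 20 seeded phantoms (10–40 structures each, default noise) the default
pipeline recovers the embedded count within ±1 with correlation ≥ 0.99
and total-volume error of a few percent (test suite, `phantom_recovery`).
Thresholded vesselness inherently adds a sub-voxel rim around each tube,
so measured volumes sit slightly above the rasterised truth; at the
chosen structure sizes this bias stays below ~8 %.

## 5. Cohort model

Per group, the joint vector (seizure duration, course from onset to
scan, VRs count, VRs volume) follows a Gaussian copula. Margins are
truncated normals whose parent mean/SD are solved (weighted least
squares, mean term dominating) so that the *post-truncation* moments
equal the configured values; the latent correlation matrix holds the
four configured cross-correlations exactly, completing the two
unspecified entries (duration–course, count–volume) by maximising the
smallest eigenvalue. This completion — rather than zero-filling followed
by a nearest-PSD projection — is essential: with the configured
cross-correlations, zeros in the free slots give a matrix with smallest
eigenvalue −0.55, and any nearest-PSD repair drags the configured
entries far outside the ±0.05 recovery tolerance. If even the best
completion is indefinite, a clipped-eigenvalue repair runs and the
generator raises, naming the worst-moved pair, when that repair moves a
configured entry materially.

Default group parameters are the published group statistics: n = 30/40/35;
durations 7.16 ± 1.23 min truncated to (5, 15] and 2.70 ± 0.45 min
truncated to (0.5, 5] (the 5-minute group boundary and the 15-minute
ceiling of the SFS definition); course 9.60 ± 1.32 / 9.40 ± 1.43 days on
(0, 15]; VRs counts 642.70 ± 100.62 / 445.80 ± 66.10 / 430.77 ± 182.55;
VRs volumes 8514.63 ± 835.33 / 6390.43 ± 692.74 / 6048.37 ± 111.50 mm³
(the control SD is kept exactly as printed although it is an outlier
against the other groups; it is configurable); WM volume, brain volume,
head circumference, age and gestational age likewise. Within-group
correlations: +0.778/+0.702/−0.812/−0.807 (long-seizure group) and
+0.563/+0.568/−0.628/−0.562 (short-seizure group). Controls carry no
duration/course and draw count/volume independently. Sex is Bernoulli
per group using the printed percentages (70 / 73.33 / 74.29 % male),
since the printed male *counts* are inconsistent with the group sizes.
Counts are rounded to integers (a ±0.5 perturbation, negligible against
SD ≈ 100).

Two bounded covariates deserve a caveat: the printed age SDs
(15–17 months on the 6–60-month range) exceed what any truncated normal
on that interval can achieve (the uniform limit is ≈ 15.6), so ages match
the configured mean exactly and approach the SD as closely as the family
allows. At n = 20 000 the generator reproduces all configured means
within 1 % and all configured correlations within 0.05 (truncation
slightly attenuates the latent correlations; the attenuation stays well
inside that band).

## 6. Statistics

*Mann–Whitney U* — U counts pairwise wins (ties half), reported as
min(U, n₁n₂ − U); the p-value is exact for n₁ + n₂ ≤ 16 with tie-free
data and otherwise the normal approximation with tie-corrected variance
and continuity correction, capped at 1. The exact path is validated
against a full-enumeration oracle in the tests; the approximation's true
worst-case error at n = 8 + 8, enumerated over all 65 possible U values,
is 0.0109. *Bonferroni* — α/m with m = 3, the three group pairs, matching
the conventional rendering .017; the number of metrics tested is not
folded into m. p-values render to three decimals with a "<.001" floor.
*Pearson* — sample r with the t-transform p on n − 2 degrees of freedom;
the panel computes the four duration/course × count/volume correlations
per seizure group and refuses controls.

*LOESS* — local linear regression on a 200-point equispaced grid over
the x-range: at each grid point the ⌈span·n⌉ nearest x-neighbours are
fitted by weighted least squares with tricube weights
w = (1 − (d/d_max)³)³; span defaults to 0.5, degree to 1, and degenerate
local designs fall back to the weighted mean with a warning. The
implementation agrees with the reference lowess implementation in
statsmodels to 1e−8 on the same grid. *Cutoff detection* — the grid
point maximising the absolute second difference of the fitted curve
(maximum curvature), excluding the outer 5 % of the grid; a signed
(maximum-convexity) variant is available. A flat profile (below 1e−9 of
the curve's range) raises rather than reporting a spurious cutoff. The
smoothed metric, span, degree and criterion are free choices — nothing
in the source analysis pins them down — so all four are configuration
keys and are recorded in every report.

A caveat on the 5-minute cutoff: under the default cohort model the
pooled count-versus-duration curve places its dominant changepoint near
4 minutes, not 5. This is a property of the generative model itself, not
of the detector: the short-seizure duration margin (2.70 ± 0.45,
truncated at 5) concentrates essentially all its mass below ~4 minutes,
and its within-group correlation (0.563 against a count SD of 66 over a
0.45-minute duration SD) forces a steep rise of expected counts toward
the top of that range — E[count | duration] climbs at ≈ 83 counts/min up
to ~4 min, *drops* across the unpopulated (4, 5.1) interval, and resumes
at ≈ 64 counts/min above it. Every curve-shape criterion we evaluated
(absolute/signed second differences at several window widths, robust
LOESS, two-segment broken-stick fits, swapped-axes readings) locates the
dominant feature at the lower shoulder. The detector itself recovers
constructed slope breaks anywhere in 3–8 minutes to within ±0.5 min at
the cohort's noise level (test suite), so the discrepancy is a statement
about the printed group parameters, not about the changepoint machinery.

Type-I error is checked under the null (all three groups from one
distribution, 2000 replicates at n = 30/40/35): the family-wise rate of
any pairwise p < .017 stays at ≈ α.

## 7. What the tests do and do not show

Everything above is validated on synthetic data whose contrast, noise
and geometry are idealised: no bias field, no cortical folding, no
motion, no multi-contrast confirmation (T1/FLAIR differential diagnosis
of other white-matter hyperintensities is out of scope). Passing tests
establish the internal correctness of the operators and the faithfulness
of the statistics to the published group parameters; they do not certify
segmentation accuracy on clinical scans. Known limitations: k-means
tissue segmentation assumes three well-separated intensity modes; a real
VRs sitting directly on the ventricle roof would merge with the
ventricle CSF component and shift the detected ventricular level;
thresholded vesselness over-measures tube volume by a sub-voxel rim; and
structures at the in-plane resolution limit (radius ≈ one voxel) are not
reliably countable in either the truth rasterisation or the detection.
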