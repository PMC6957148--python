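# Methods

## Scope and data model

The package operates on a 3D CT volume in Hounsfield units and a
co-registered binary mask of the pancreas on the *same* grid. Masks are
strictly binary (any nonzero label is foreground); there is no
partial-volume weighting and no resampling stage — features are computed
on the native grid using the header spacing in mm, which is typically
strongly anisotropic for venous-phase abdominal CT (sub-millimetre
in-plane, 2.5–5 mm slices). Header rescale slope/intercept are applied at
read time so values are calibrated HU; no windowing or clipping is applied
by default. DICOM ingestion, registration and automatic segmentation are
out of scope.

## First-order features

Computed on the marginal distribution of HU inside the ROI. SD and
variance use the n−1 denominator (a sample from an organ, not a census).
Skewness is the adjusted Fisher–Pearson coefficient and kurtosis the
non-excess moment ratio m₄/m₂² (normal ≈ 3); both are the conventions of
mainstream statistical packages, and both are selectable
(`skewness_convention`, `kurtosis_convention`). Entropy and homogeneity
are histogram functionals on fixed-width bins (default 1 HU, left-closed
right-open, edges anchored at integer multiples of the width so binning is
deterministic and sample-independent):

* entropy `−Σ p_b ln p_b` in nats. For a Gaussian HU field of SD σ with
  1-HU bins this approaches the differential entropy ½ln(2πeσ²) — about
  4.9 nats at σ ≈ 32 HU, which is the magnitude scale expected for
  pancreatic parenchyma and the basis for choosing the natural log as
  default (log2/log10 available).
* homogeneity `Σ p_b²`, the histogram uniformity: 1 for a constant
  region, ≈ 1/(2σ√π) ≈ 0.009 for the same Gaussian field.

Statistics whose preconditions fail (skewness with n < 3, kurtosis with
n < 4, either with zero variance) are NaN, the pipeline-wide undefined
marker; they propagate into tables rather than raising.

## Shape features

All quantities are physical and anisotropy-aware.

* **Volume**: voxel count × voxel volume, in cm³.
* **Surface area**: exposed voxel-face counting — a face is exposed when
  its 6-neighbour is background or off-grid; each face contributes its
  physical area (s_y s_z, s_x s_z or s_x s_y). Deterministic and exactly
  oracle-checkable, unlike a mesh estimate; a marching-cubes alternative
  was deliberately not made the default for that reason. Face counting
  overestimates the area of smooth anatomical surfaces (the Manhattan
  effect), which is acceptable for between-group comparison since the bias
  is shared.
* **Effective diameter**: the maximum pairwise distance between foreground
  voxel centres (3D caliper length), computed on the convex hull with an
  exact fallback for small or degenerate point sets. This is an organ
  *length* (~135 mm for a pancreas), not the equivalent-sphere diameter
  (~48 mm for the same organ); the length interpretation is the one
  consistent with the reported magnitude of the measurement.
* **Sphericity**: `(V/V_circ)^{1/3}` with `V_circ` the sphere on the
  caliper diameter, equivalently `d_equiv/d_max`. The cube root maps the
  raw volume ratio (~0.05 for a pancreas) onto the reported ~0.3 scale and
  makes the quantity a dimensionless diameter ratio. The max-caliper
  sphere slightly over-bounds the true minimal enclosing sphere for some
  shapes; for elongated organs the two coincide along the long axis.
* **Discrete compactness**: Bribiesca's normalized contact-surface
  compactness `C_d = A_c / (3(n − n^{2/3}))` with `A_c` the number of
  6-connected contact faces; 1 for perfect k³ cubes, 0 for fully
  disconnected voxels, defined as 1 for n = 1. Note that published
  per-group summaries of an in-house implementation of this quantity can
  include negative values, which are impossible under this definition
  (C_d ∈ [0,1]); such values indicate a different normalization (possibly
  standardized scores) and are not emulated here.

## GLCM features

Gray levels are quantized at 1-HU resolution anchored at the region
minimum (`level = floor((HU − min)/w)`), which makes every GLCM feature
invariant to adding a constant HU offset. The co-occurrence matrix
accumulates, over the 13 unique direction vectors of the 26-neighbourhood
at Chebyshev distance 1, every voxel pair that lies entirely inside the
mask; pairs are counted in both orders (symmetric matrix) and normalized
to sum to 1. One aggregated matrix is used rather than per-direction
feature averaging; per-direction analysis can be emulated by passing a
single offset. Offsets live in index space: on a 0.7 × 0.7 × 5 mm grid
the z-neighbour is physically ~7× farther than an in-plane neighbour, so
an `"inplane"` offset set is provided for spacing-sensitive work.

Features: contrast `Σ p(i−j)²w²` (HU² of the quantized scale), entropy
`−Σ p ln p`, ASM `Σ p²`, IDM `Σ p/(1+(i−j)²)`, and "moments" defined as
the mean absolute gray-level difference `Σ p·|i−j|^k`, k = 1 by default
(the order is configurable; the quantity is a difference moment, the
simplest member of that family). Fine 1-HU quantization is the default
because it reproduces the reported magnitude of GLCM contrast
(≈ 800–1700 HU²) for noisy CT; 25-HU bins would compress contrast to
order 1–10. The entropy log base is a config knob recorded in output
metadata; note that reported GLCM-entropy values near 4.0 alongside ASM
≈ 1.5×10⁻⁴ are more consistent with a log10 convention (ln of ~6900
effective states ≈ 8.8, log10 ≈ 3.8) — with the natural-log default this
implementation prints ≈ 9.5 on comparable textures. All between-group
conclusions are invariant to the base, which rescales entropy
monotonically.

## Cohort statistics

Group labels are `case`/`control`. Per feature, the two-group comparison
is the pooled-variance Student t test by default — "the independent
samples t test" of standard statistical software — with Welch and
Mann-Whitney variants (Mann-Whitney uses exact enumeration when
n₁+n₂ ≤ 12 and there are no ties, otherwise the tie-corrected normal
approximation). No multiple-testing correction is applied across the 17
features by default, mirroring common practice in this literature; a
screening α of 0.05 feeds the multivariable stage.

The multivariable model is a binary logistic regression on the screened
features, reduced by backward elimination: refit without each feature,
compute the likelihood-ratio p (χ², 1 df), and remove the feature with
the largest p ≥ 0.10, repeating until all survivors are below the
threshold (Wald-based removal selectable). Predictors are standardized
internally for numerical stability; reported coefficients and Wald CIs
are translated back to per-unit scale, with per-SD odds ratios reported
alongside because per-unit ORs of features spanning four orders of
magnitude (e.g. surface area in mm²) are uninterpretable at display
precision. Complete separation — common in small matched cohorts with
strong features — is detected (failed MLE or |per-SD log-odds| > 15) and
*flagged* on the retained term rather than dropped: a diverging OR is a
statement about the data, not a numerical accident. Covariates (age, BMI)
are carried but not modelled by default, matching a matched-pairs design
where adjustment is by construction.

ROC analysis is per feature: the empirical curve over all observed
thresholds, AUC by trapezoid (equal to the midrank Mann-Whitney estimate
U/(n₁n₂), which the tests verify independently), direction auto-detected
so AUC ≥ 0.5, and the optimal cutoff maximizing Youden's J with ties
broken toward the cutoff nearest the case-group median (a rule stated
explicitly because the criterion alone is frequently tied on small
cohorts).

## Synthetic phantoms and cohorts

The generator emulates what the analysis *assumes about* pancreatic CT,
not pancreatic anatomy: a lobulated ellipsoid (default half-axes
65 × 22 × 10 mm → ~60 cm³, ~130 mm long; relative radial perturbation
0.15 over 12 seeded bumps) rasterized on a 0.7 × 0.7 × 5 mm grid, filled
with white Gaussian noise smoothed at a correlation length (mm) and then
affinely renormalized so the within-mask mean/SD hit their targets
exactly. The smoothed-Gaussian field is the simplest model in which the
marginal SD (first-order variance) and the neighbour similarity
(second-order contrast/IDM) are independently tunable — exactly the
first-order/second-order distinction the analysis trades on.

Control-population defaults: mean HU 110.3 ± 20.4 between subjects, SD
31.8 ± 6.1, correlation length 0.7 ± 0.1 mm, length/thickness scale
factors 1 ± 0.07/0.06, lobulation 0.15 ± 0.04 (Gaussian draws truncated
to valid ranges). The diabetic-like effect profile shifts per-subject
parameters: mean HU −17.1, noise SD +5.2, long axis ×0.93 at constant
thickness (raising sphericity ~7%), correlation length ×3.1 (cutting
GLCM contrast roughly in half while first-order variance *rises* — the
signature opposite movement of the two dispersion measures). Seeding uses
one master seed with per-subject `SeedSequence(master, spawn_key=(group,
index))` substreams, so cohorts are bit-reproducible and individual
subjects are stable when the cohort grows.

What the phantoms do **not** model: CT physics (beam hardening,
reconstruction kernels, dose noise texture), anatomical neighbours and
ducts, segmentation error, scanner differences. Passing the synthetic
validation therefore demonstrates that the *pipeline* recovers injected
statistical structure of the stated kind — it is not evidence about real
diabetic pancreata.

## Simulation sizes and numerical choices

Validation batteries use a reduced-resolution phantom profile (in-plane
spacing coarsened to 1.4 mm, same geometry and noise model, ~6·10³ mask
voxels) so that twenty 30-vs-30 cohorts — 1200 phantoms — run in under a
minute; the study-scale acceptance run uses native 0.7 mm resolution
(~2.4·10⁴ mask voxels) at n = 51/group. Logistic fits use Newton/IRLS
(tol 1e-8, 100 iterations) with a BFGS fallback; histogram and
quantization edges are anchored (no data-driven binning); all undefined
quantities are NaN-propagated; report files are written with fixed float
formatting so equal runs are byte-identical.

## Known limitations

* The caliper-diameter circumscribed sphere can exceed the minimal
  enclosing sphere by up to ~15% for some compact shapes, inflating
  sphericity's denominator; irrelevant for elongated organs.
* Face-count surface area is a Manhattan upper bound on smooth-surface
  area.
* The GLCM "moments" feature is one member of a family; published
  summaries under that name may use a different order or normalization.
* Backward elimination at p_remove = 0.10 retains a pure-noise feature
  with roughly that probability per candidate — an irreducible property
  of the selection rule, visible in the selection-recovery simulations.
* Near-separated logistic fits report divergent ORs with flags; their
  Wald p-values are meaningless by construction and should be read via
  the likelihood-ratio elimination trace instead.
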