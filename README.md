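# pantex — 3D CT texture analysis of the pancreas

`pantex` quantifies the pancreatic parenchyma on contrast-enhanced CT and
asks whether its texture separates two groups of subjects (e.g. diabetic
patients vs matched controls). Diabetes remodels the pancreas — β-cell
loss, fibrosis, fatty replacement, atrophy — and those histologic changes
plausibly alter both the attenuation statistics and the spatial texture of
the organ long before anything is visible to a radiologist. The package is
aimed at quantitative-imaging researchers who have a CT volume plus a
manually segmented pancreas mask per subject and want a reproducible,
fully scripted version of the classic radiomics workflow: feature
extraction → univariate screen → multivariable model → ROC cutoffs.

## What it computes

**17 features per segmented region** (the canonical CSV column order):

* *First order* (histogram of HU values inside the ROI): mean attenuation,
  SD, variance, skewness (adjusted Fisher–Pearson), kurtosis (non-excess,
  normal ≈ 3), histogram entropy `−Σ p_b ln p_b`, and homogeneity
  (histogram uniformity `Σ p_b²`), on fixed 1-HU bins.
* *Shape* (binary mask, anisotropy-aware, mm units): volume
  `N·s_x s_y s_z`, surface area by exposed voxel-face counting, effective
  diameter (maximum 3D caliper distance between voxel centres), sphericity
  `(V / V_circ)^{1/3} = d_equiv / d_max` with `V_circ` the sphere
  circumscribed on the caliper diameter, and Bribiesca's discrete
  compactness `C_d = A_c / (3(n − n^{2/3}))` from the 6-connected
  contact-face count `A_c`.
* *GLCM* (gray-level co-occurrence matrix, 1-HU quantization anchored at
  the region minimum, the 13 unique 3D directions at Chebyshev distance 1,
  symmetrized and normalized): contrast `Σ p_{ij}(i−j)² w²`, entropy
  `−Σ p_{ij} ln p_{ij}`, angular second moment `Σ p_{ij}²`, inverse
  difference moment `Σ p_{ij}/(1+(i−j)²)`, and the mean absolute
  gray-level difference `Σ p_{ij}|i−j|`.

**Cohort statistics**, statsmodels-style: build a `TextureCohortModel`
from a per-subject feature table, `fit()` it, and read everything off the
results object — per-feature pooled-t (or Welch / Mann-Whitney)
comparisons, the univariate screen at α = 0.05, backward-elimination
logistic regression (likelihood-ratio removal at p ≥ 0.10) with per-unit
and per-SD odds ratios and 95% Wald CIs, and per-feature ROC analysis with
the Youden-index optimal cutoff. Near-separation (the source of the
astronomically large odds ratios these small matched cohorts are known
for) is detected and flagged, never silently dropped.

**Synthetic cohorts**: since no imaging data ship with the package, a
seeded generator produces pancreas-like phantoms — lobulated ellipsoids
(~40–70 cm³, ~100–145 mm long) on an anisotropic CT grid (0.7 mm in-plane,
5 mm slices) filled with correlated Gaussian noise whose within-mask
mean/SD and correlation length are controlled — and two-group cohorts
whose case group shifts in the directions reported for diabetic pancreata:
lower mean attenuation, higher variance, higher sphericity, lower GLCM
contrast.

## Worked example

```python
from pantex import CohortSpec, TextureCohortModel, simulate_feature_table
from pantex.simulate import REDUCED_PHANTOM

spec = CohortSpec(n_per_group=30, seed=7, base_phantom=REDUCED_PHANTOM)
table, manifest = simulate_feature_table(spec)   # 60 phantoms -> 17 features each
results = TextureCohortModel(table).fit()
print(results.summary())
```

prints (abridged):

```
Univariate screen (alpha=0.05): mean_attenuation, sd, variance, entropy,
homogeneity, surface_area_mm2, effective_diameter_mm, volume_cm3,
glcm_entropy, glcm_asm, glcm_idm

Multivariable logistic model (backward elimination):
  sd                     OR=62.57 (95% CI 7.693e-16–5.09e+18) p=0.8351  [near-separation]
  glcm_idm               OR=inf (95% CI 0–inf) p=0.8494  [near-separation]
  eliminated: variance (removal p = 1)
  ...

ROC analysis of retained features:
  sd                     AUC=0.822 cutoff=33.45 sens=83.3% spec=80.0% (cases higher)
  glcm_idm               AUC=0.798 cutoff=0.03382 sens=83.3% spec=70.0% (cases higher)
```

Reading this: eleven features differ univariately between the simulated
diabetic-like and control groups; backward elimination keeps an HU-SD term
and a GLCM inverse-difference-moment term, but flags both as
near-separated (at n = 30/group the two groups barely overlap on those
axes, so the MLE odds ratios diverge — report the AUCs and cutoffs, not
the ORs). The SD cutoff of 33.45 HU classifies cases with 83% sensitivity
and 80% specificity on this cohort.

The same run from the shell:

```bash
pantex reproduce --n-per-group 30 --seed 7 --out-dir runs/demo
```

writes `features.csv`, `manifest.csv`, `report.csv`, `roc.csv`,
`report.json`, `config.json` and `run.json`; repeating the command with
the same seed reproduces every file byte for byte. `pantex extract`,
`pantex cohort` and `pantex simulate` run the individual stages on your
own NIfTI volumes and feature tables.

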