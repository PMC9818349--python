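# Methods

## The model

`ssmpca` implements the scaled subprofile model (SSM) family of spatial
covariance analyses for metabolic brain images. Each subject's image is
assumed to be generated as

    raw_i(v) = g_i * exp(GMP(v)) * exp(sum_j s_ij * GIS_j(v))  (+ noise)

where `g_i` is a subject-specific multiplicative global factor (scanner
sensitivity, injected dose, global metabolism), `GMP` is a group mean
log-profile shared by everyone, `GIS_j` are spatial covariance patterns,
and `s_ij` is subject *i*'s expression score on pattern *j*. Taking
natural logs makes the model additive; removing each subject's own mean
over the analysis mask (row centering) eliminates `log g_i` exactly, and
removing the per-voxel mean of the row-centered data (the stored GMP)
leaves residual subject profiles. PCA of those residuals estimates the
patterns and scores.

Because cohorts have tens of subjects and thousands of mask voxels, the
PCA is solved in subject space: the eigendecomposition of the
subjects-by-subjects Gram matrix `R Rᵀ` shares the nonzero spectrum of
the voxel-space covariance `Rᵀ R`, and `GIS_j = Rᵀ u_j / sqrt(λ_j)`.
A test verifies this equivalence against a direct voxel-space
decomposition. Components with eigenvalue below `1e-12` of the largest
are treated as numerical null space and dropped.

## Derivation pipeline and its conventions

1. **Mask.** A voxel enters the analysis iff, for every subject, its
   intensity is at least `mask_threshold` (default 0.35) times that
   subject's mean over its strictly positive voxels. "Mean brain
   activity" is taken over positive voxels, and per-subject masks are
   intersected: this guarantees strictly positive masked intensities for
   every subject, so the log transform is always defined. The threshold
   is relative to each subject's own mean, making the mask invariant to
   global rescaling of any subject.
2. **Log transform.** Natural log, fixed. The base only rescales scores
   globally and is removed by Z-standardization, but fixing it keeps
   results bit-stable.
3. **Double centering.** Rows (subjects) first, then columns (voxels).
   The final residuals are order-independent, but the stored GMP is not:
   it is defined as the column means of the *row-centered* matrix because
   prospective scoring must reuse exactly this GMP.
4. **PCA and variance cutoff.** Components are retained in descending
   eigenvalue order until their cumulative variance fraction reaches
   `variance_cutoff` (default 0.50). The component that crosses the
   boundary is included; an exact tie at the cutoff also includes the
   boundary component.
5. **Component selection.** A pooled-variance (Student) two-tailed
   two-sample t-test on each candidate component's subject scores,
   disease vs control, retained at `p < alpha_select` (default 0.05).
   Before testing, each candidate's sign is oriented so the disease-group
   mean score exceeds the control-group mean; higher expression is
   therefore always disease-like. Candidates are exactly the
   variance-selected prefix.

Scores are unnormalized projections onto unit-norm patterns (no
eigenvalue weighting): the simplest convention consistent with the
prospective-scoring equivalence below, and harmless because all reported
scores are Z-standardized.

## Prospective scoring (TPR)

A new subject is scored by restricting its image to the stored mask,
taking logs, subtracting the subject's own mask mean, subtracting the
stored GMP, and projecting onto a pattern's voxel weights. On the
derivation subjects this reproduces the PCA scores to machine precision
(verified at 1e-8 relative tolerance per component and for the
composite) — the central correctness check of the scoring path. Scoring
is invariant to global rescaling of the input volume and affine in the
pattern weights.

## Cross-validation and the composite pattern

Selected components are re-tested on held-out cohorts: every disease
cohort (derivation + validation) is paired with every control cohort
(four pairs when one validation cohort of each role is supplied), and a
component survives only if the pooled t-test separates each pair at
`p < 0.05`. With no validation cohorts the candidate set passes through
unchanged (an empty conjunction).

Surviving components are combined with weights from a binary logistic
regression of disease status (disease = 1) on the unstandardized
component scores of the derivation subjects only — validation cohorts
stay held out. The intercept is stored but excluded from the voxel
weights, since a constant shift is absorbed by Z-standardization. If the
classes are linearly separable the maximum-likelihood fit diverges; the
fit is then repeated with a fixed ridge penalty of `1e-4` on the slopes
(never the intercept) and the result is flagged. Separation is detected
by optimizer failure, exploding coefficients, or every fitted probability
within `1e-3` of its label.

Composite voxel weights are `sum_j c_j * GIS_j`. The Z reference for
subject scores is the derivation control group's composite raw scores
(mean and sample sd, n−1 denominator), so derivation controls have Z
mean 0 and sd 1 exactly. The displayed voxel map is Z-transformed after
combination, over the mask.

## Smoothing

Separable Gaussian smoothing parameterized by FWHM in mm
(`sigma = FWHM / (2 sqrt(2 ln 2)) / voxel_size` per axis), with a
zero-padded boundary: outside the field of view is treated as zero
signal. The pipeline default is 12 mm FWHM applied at load time;
`fwhm = 0` disables it. Smoothing is applied immediately after loading,
before any masking.

## Group statistics

Pattern-expression score tables are compared with a gated battery:

- **Gates.** Lilliefors normality per group and Levene variance
  homogeneity across groups, both at the fixed gate threshold
  `p > 0.05`. All groups must pass both gates for the parametric branch.
- **Parametric branch.** One-way ANOVA omnibus, pairwise pooled-t
  post-hocs.
- **Nonparametric branch.** Kruskal–Wallis omnibus, pairwise
  Mann–Whitney post-hocs.
- **Multiplicity.** Post-hoc p-values are Holm-adjusted as one family
  (six pairs for four groups); the omnibus test is not in the family.

The Lilliefors p-value comes from a seeded Monte-Carlo null (default
10 000 standard-normal replicates of the sample size, cached per size)
rather than tabulated critical values, for exact reproducibility; the
null distribution is location/scale-free so standard-normal draws
suffice. The Mann–Whitney p is exact by enumeration of all rank
assignments when `n_a + n_b <= 12` (valid under ties) and a
tie-corrected normal approximation otherwise. Levene with zero spread in
every group returns statistic 0, p 1 (no evidence of unequal variances)
rather than 0/0. The whole battery's omnibus type-I error measures
~0.053 over 2 000 null simulations — the small excess over the nominal
0.05 is the usual cost of conditioning on pretests.

A chlorpromazine-equivalent utility converts antipsychotic doses via
user-supplied per-drug multipliers (`equivalent = dose × m_drug`). The
shipped ratio table (`examples/cpz_ratios_example.csv`) contains
illustrative values only and must be replaced with clinically sourced
ratios before any real use.

## Synthetic cohorts

The generator emulates exactly the structure the model assumes: an
ellipsoidal brain with a smooth radial base profile
`B = 100 (1 − 0.5 r²)` (r the normalized ellipsoidal radius; positive,
highest centrally, half at the rim), one smooth zero-mean unit-norm
embedded pattern `P`, and per subject

    raw_i = g_i * B * exp(a_i P + eps_i)  inside the brain, 0 outside,

with `log g_i ~ N(0, global_sd²)` (default 0.2), group-dependent loading
`a_i ~ N(mean_group, 1)` (defaults: controls 0, disease 2.5,
intermediate scored groups 1 and 2), and a smooth log-domain noise field
rescaled to per-voxel sd `noise_sd` (default 0.05). Pattern and noise
fields are white noise smoothed to 6 and 4 voxels FWHM respectively and
renormalized; smoothing reuses the cohort smoothing kernel, and the
voxel-to-mm FWHM conversion assumes isotropic grids. Default cohort
sizes mirror a realistic derivation study: 19 + 19 derivation, 15 + 18
validation, 14 + 14 prospectively scored, on a 24³ grid of 2 mm voxels.
Noise is added in the log domain so the model is exactly well-specified;
a `raw_noise_sd` switch adds raw-domain additive noise for robustness
checks under deliberate misspecification.

What the phantom does *not* emulate: anatomy (no tissue classes, no
left-right asymmetries in the base profile), scanner physics
(attenuation, reconstruction artifacts, resolution non-uniformity),
multiple overlapping disease patterns, or registration error. Passing
recovery tests therefore demonstrates correctness of the estimation
machinery under its own assumptions, not robustness to real-data
violations of them.

## Problem sizes in tests

End-to-end checks run at the default study size (24³ grid, 71–99
subjects, 10 seeds); calibration checks use 200 derivation simulations
and 500 null score-table simulations; several unit tests use a 16³ grid
with 8–10 subjects per group. At these sizes the complete suite runs in
about a minute.

## Known limitations

- Volumes must be pre-normalized to one grid; no resampling or
  registration is performed, and orientation metadata is carried but
  never interpreted.
- Analyze-format support is read-only; all outputs are NIfTI-1.
- No voxel-wise inference on patterns (no permutation or bootstrap
  thresholds on the maps).
- Model directories store maps as float32 NIfTI; scores and scalars are
  kept at full precision in the JSON sidecar, so reloaded patterns score
  identically while reloaded GIS maps round to float32.
- The nonparametric branch is fixed to Kruskal–Wallis / Mann–Whitney;
  alternative rank procedures are not provided.
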