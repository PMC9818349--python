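# ssmpca

Scaled subprofile model PCA (SSM-PCA) for deriving disease-related
metabolic covariance patterns from brain FDG-PET volumes and scoring new
subjects against them.

The motivating application is parkinsonism: the Parkinson's
disease-related pattern (PDRP) is a spatial covariance pattern of
regional glucose metabolism whose per-subject expression score rises
with disease, and whose prospective expression can be measured in other
populations — for instance schizophrenia patients with and without
neuroleptic drug-induced parkinsonism (DIP). The package is for imaging
researchers who have spatially normalized volumes on a common grid and
want a reproducible, fully tested derivation and scoring pipeline with
a ground-truth phantom generator for validation.

## The method

Given subject images `raw_i(v)` on a shared voxel grid, SSM assumes a
multiplicative global factor and log-linear pattern expression:

```
log raw_i(v) = log g_i + GMP(v) + Σ_j s_ij · GIS_j(v) + ε_i(v)
```

The pipeline: (1) mask voxels above a relative intensity threshold
(default 0.35 of each subject's mean brain activity, intersected across
subjects); (2) natural-log transform; (3) double centering — subtract
each subject's own mean (removing `log g_i`), then the per-voxel group
mean profile GMP; (4) PCA of the residual profiles in subject space,
yielding unit-norm voxel patterns GIS_j and subject scores
`s_ij = r_i · GIS_j`; (5) keep the leading components explaining the
first 50 % of variance, then those whose scores separate disease from
control by Student's t-test (p < 0.05); (6) cross-validate survivors on
held-out cohorts (all disease-vs-control pairs must separate); (7)
combine them with logistic-regression weights into one composite
pattern. New subjects are scored prospectively by the topographic
profile rating (TPR) — the projection of their residual log profile onto
the composite — and reported as Z-scores standardized by the derivation
control group. Score tables are compared across groups with a gated
ANOVA / Kruskal–Wallis battery with Holm-corrected post-hocs.

See `docs/methods.md` for every convention, default and limitation.

## Worked example

Simulate a phantom study (six groups sized like a realistic derivation
cohort, 24³ grid), derive the pattern from the PD and control groups,
validate on held-out groups, and score everyone:

```python
import numpy as np
import ssmpca as sp

cohort = sp.simulate_cohort(sp.SynthConfig(seed=7))
model = sp.derive_ssm(cohort.subset(["PD", "C"]), "PD", "C")

validation = [("PDv", "disease", cohort.subset(["PDv"])),
              ("AIMN", "control", cohort.subset(["AIMN"]))]
surviving, _ = sp.cross_validate_components(model, validation)
groups = np.asarray(model.groups)
sel = np.flatnonzero((groups == "PD") | (groups == "C"))
coef, intercept, flag = sp.fit_logistic_combination(
    model.scores[np.ix_(sel, surviving)], (groups[sel] == "PD").astype(int))
pattern = sp.compose_pattern(model, surviving, coef, intercept, flag)
scores = sp.score_cohort(cohort.volumes, pattern)
print(scores.groupby("group").z_score.mean().round(2))
```

Output:

```
group
AIMN     -0.07
C        -0.00
DIP       1.69
PD        2.24
PDv       2.02
nonDIP    0.97
```

The derivation keeps five components to reach 50 % of variance (the
first explains 30 %), exactly one passes the t-test and survives all
four cross-validation pairs, and its logistic coefficient is 3.32. The
derivation controls sit at Z = 0 by construction; mean expression rises
monotonically from controls through the intermediate scored groups to
the PD groups — the expected uptrend. Against the generator's ground
truth, the composite pattern correlates with the embedded pattern at
r = 0.958 and subject Z-scores track the true loadings at r = 0.961;
the gated comparison of the C / nonDIP / DIP / PD score table takes the
parametric branch with ANOVA p = 7.8e-09.

The same pipeline runs from the shell:

```
ssmpca simulate --out cohort --seed 7
ssmpca derive   --manifest cohort/manifest.csv --out deriv
ssmpca score    --manifest cohort/manifest.csv --pattern deriv/pattern --out scores.csv
ssmpca compare  --scores scores.csv --out stats.json
```

Each subcommand accepts `--config config.yaml` (group labels and roles,
SSM thresholds, smoothing FWHM, statistics alphas, generator settings)
and echoes its resolved configuration into the output directory.

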