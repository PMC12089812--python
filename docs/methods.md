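# Methods

`neuronorm` implements an individual-level analysis pipeline for regional
brain morphometry: sex-specific normative models turn a subject's regional
measures into deviation z-scores, which feed extreme-deviation burden
statistics, group prevalence comparisons, outcome prediction, case-control
classification, and a global brain-age-gap analysis. Because the clinical
datasets such pipelines are applied to are typically access-restricted, the
package carries a first-class synthetic-cohort generator with known ground
truth; every statistical contract in the pipeline is validated against that
ground truth.

## Normative model

For each of the 150 regional features (68 Desikan–Killiany cortical
thickness, 68 cortical surface area, 14 Aseg subcortical volumes) and each
sex, the normative model is an ordinary least-squares regression

    y = β₀ + β₁·age^p₁ + β₂·age^p₂ + γ₁·ICV + γ₂·meanCT + γ₃·meanSA + ε

with degree-2 fractional-polynomial (FP2) powers (p₁, p₂) drawn from the
conventional set {−2, −1, −0.5, 0, 0.5, 1, 2, 3}, where age⁰ ≡ ln(age) and
a repeated power contributes age^p·ln(age) as the second term. The three
global measures (intracranial volume in mm³, mean cortical thickness in mm,
mean surface area in mm²) enter untransformed and linearly.

The power pair is selected per feature and sex by 5-fold cross-validated
mean squared error over all 36 pairs, with ties broken toward the
lexicographically smaller pair. Folds are assigned over subjects sorted by
identifier, so the fit is invariant to the row order of the input table.
Because all features of one sex share the same candidate design matrices,
the bank fit solves each fold once with a multi-response least squares and
scores all 150 features simultaneously.

The deviation z-score is z = (observed − predicted) / RMSE, where RMSE is
the root mean squared residual of the final full-sample refit — a single
global residual scale per model, not an age-varying one. Positive z means
the measure exceeds the normative expectation. Extremes are classified with
strict inequalities at ±1.96 (infranormal z < −1.96, supranormal z > 1.96),
the bounds of the central 95% of a standard normal (2.5% per tail); the
threshold is configurable for sensitivity analyses.

Ages outside the training range produce extrapolated predictions with a
warning rather than an error, since clinical cohorts normally sit inside a
lifespan reference range. Degenerate designs (constant age, rank deficiency
after column normalisation) are errors. Model banks serialise to JSON and
reload with bit-identical predictions.

### A note on curve identifiability at the age boundary

With a lifespan reference of 2000 subjects per sex, competing FP2 families
are often statistically indistinguishable in-sample: two families that
differ by several percent at the sparse low-age boundary (ages 3–5 hold
about 2% of a uniform age draw) can differ by less than the noise in total
residual error, and selection cannot do better than that information limit
— the fitted curve with the *true* powers already carries boundary
estimation error of comparable size. Recovery of the generating curve is
therefore assessed by the mean relative deviation across the age range
(with a coarse pointwise guard against gross divergence), which is the
quantity the data can actually pin down at this scale. In-range predictions
— and hence z-scores — are unaffected; this is purely a statement about
pointwise curve values where the reference is thinnest.

## Deviation burden and group comparisons

Per region and direction, prevalence is 100·k/n over the group. Per
subject, burden is the count of regions beyond threshold, and the
"any-region" burden indicates at least one extreme. Group differences in
prevalence use the pooled-variance two-proportion z-test without continuity
correction (p = 2·(1 − Φ(|z|))); the uncorrected pooled variant is the one
consistent with the published burden p-values this package reproduces
(p = 0.083 for 41/83 vs 39/61; p = 0.065 for 52/83 vs 47/61). A degenerate
pooled proportion (0 or 1) yields p = 1 with a warning. Multiplicity across
regions × directions is controlled with Benjamini–Hochberg FDR at q = 0.05
(statsmodels implementation; validated in tests against a brute-force
step-up oracle).

## Outcome prediction and classification

Continuous outcomes (YMRS, MADRS, IQ) are predicted from either observed
features or z-scores by ridge regression with penalty strength 1.0 on
features standardised within each training fold (the penalty is a flag; the
ambiguous convention where "α" may denote an elastic-net mixing weight is
resolved as an L2 strength, since the method is ridge). Performance is
MAE, RMSE and the per-fold Pearson correlation between observed and
predicted values, averaged over 10 folds.

Significance comes from a permutation null: the outcome vector is permuted
(equivalent to shuffling the subject-to-feature-row linkage), the full CV
rerun, and p computed with add-one smoothing, e.g.
p_r = (1 + #{perm r ≥ true r}) / (1 + n_perm); the favourable direction is
reversed for error metrics. A plain-proportion variant is available by
flag. The default permutation count is 100 000; the solver makes this
tractable by precomputing, per fold, the standardisation statistics and the
Cholesky factor of (XᵀX + αI), which depend only on the feature rows —
each permutation then costs two triangular solves, and permutations are
evaluated in vectorised blocks.

Case-control classification uses a linear SVM (C = 1.0) under stratified
10-fold CV with per-fold standardisation; held-out decision scores are
pooled across folds and summarised by rank-based ROC/AUC (ties averaged;
all-tied scores define AUC = 0.5).

## Global brain-age gap

A sex-specific brain-age model is ridge regression of age on the
standardised 150-feature vector plus the three global covariates, with the
penalty chosen from a log-spaced grid (10⁻¹…10⁵) by efficient leave-one-out
generalised cross-validation. G-brainAGE = predicted − chronological age;
positive values indicate apparently accelerated ageing.

Raw gaps are biased by regression to the mean: with shrinkage, predictions
tilt toward the training mean age, so gaps correlate negatively with age.
The correction regresses out-of-fold reference gaps on a polynomial of age
and subtracts that trend from all subsequent gaps. The default degree is 3
rather than 1: a linear map from morphometry to age leaves a *curved*
mean-gap-versus-age profile, because feature trajectories are steepest in
youth, and a linear residualisation leaves a residual trend concentrated
exactly in the young age bands where clinical cohorts sit. With the cubic
correction, injected global offsets of −3, −1 and +2 years are recovered
within a few tenths of a year in the package's recovery experiments
(tests/test_acceptance.py); `bias_degree=1` restores the plain linear
variant and `bias_correction=False` disables correction entirely.

Clinical correlates of the gap table: Pearson correlation with the exact
t-based p on n − 2 df; independent-samples t-test between medication
subgroups (equal-variance by default, Welch by flag); and an OLS moderation
model gap ~ onset + sex + onset×sex, whose interaction test is invariant to
affine recoding of sex.

## Synthetic cohorts

Each feature follows a smooth sex-specific FP2 age trajectory plus linear
loadings on the generated global covariates plus i.i.d. Gaussian noise;
since the trajectory powers come from the permitted FP set, the normative
model family is correctly specified for these data and recovery tests have
an exact oracle (`ground_truth_mean`). Default trajectory shapes follow the
broad strokes of lifespan morphometry: thickness declines roughly
log-linearly from childhood (regional noise sd 0.07–0.12 mm); area peaks in
adolescence and declines slowly (noise 5–9% of the regional mean); 
subcortical volumes shrink gradually and load on ICV (noise 5–8%); ICV
plateaus after childhood and is ~10% larger in males. Reference ages are
uniform over 3–90 years by default (a user-supplied sampler is accepted);
sexes are assigned in exact proportion.

Case cohorts add three configurable mechanisms: per-feature additive effect
shifts; a global brain-age offset δ, implemented by generating all brain
features (covariates included) at effective age = chronological age + δ
while storing chronological age unchanged; and clinical outcomes as linear
combinations of the noise-free feature values plus Gaussian noise,
truncated to valid ranges (YMRS, MADRS ≥ 0). By default the clinical models
carry zero feature weights — outcomes independent of brain structure —
matching a first-episode cohort in which morphometry has no detectable
predictive value. Default sizes are desk-scale study conditions: reference
2000 per sex, cases n = 83 aged 14–35, comparators n = 61 aged 16–37.

Everything is deterministic given (spec, seed): identical specs produce
byte-identical tables.

What the generator does *not* emulate: site/scanner effects (no
harmonisation is needed or provided — a pass-through hook marks where
ComBat-style harmonisation would sit for multi-site data), spatial
correlation between regions beyond what the shared global covariates
induce, non-Gaussian residuals, heteroscedasticity across age, missing
data, and longitudinal structure. Passing calibration and null-control
tests on these cohorts therefore demonstrates the statistical machinery is
correct and unbiased under the stated generative assumptions, not that real
MRI-derived tables satisfy those assumptions.

Null-configuration experiments (zero effects, zero offset) use identical
age ranges for cases and controls. This matters: features encode age well
enough that a classifier can decode it almost perfectly, so even modest
age-range differences between exchangeable-in-every-other-way groups yield
above-chance AUC through demographics alone — a real covariate effect, not
a miscalibration.

## Numerical and testing choices

- Least squares via LAPACK `lstsq` on subject-sorted rows: results
  independent of input row order.
- Ridge fold solver: Cholesky of (XᵀX + αI), positive-definite for α > 0;
  constant feature columns get unit scale after centering (they carry no
  signal and no influence).
- Per-fold Pearson r with a zero denominator (constant predictions or
  constant held-out outcome) is defined as 0.
- Calibration acceptance (held-out z mean within ±0.05, sd within ±0.05,
  tail rate 5% ± 1% per feature) averages per-feature statistics over three
  independent train/held-out replicates at 2000/sex, so the check measures
  systematic miscalibration rather than single-draw Monte-Carlo noise.
- Problem sizes in tests and in `scripts/acceptance.py` are desk-scale
  choices: reference 2000/sex; 200-replicate null and recovery experiments;
  permutation-null calibration at n_perm = 199 with 400–500 replicates;
  the 100 000-permutation default applies to real analyses.

## Known limitations

- A single global RMSE per model: no age-varying (heteroscedastic) spread,
  so z-scores are exact only under homoscedastic residuals.
- The brain-age learner is a penalised linear model on the same 150-feature
  representation — a deliberately simple stand-in adequate for the
  pipeline's statistical contracts, not a reimplementation of any specific
  published brain-age architecture.
- Pointwise normative-curve values at the sparse extremes of the reference
  age range carry irreducible estimation error at desk scale (see above).
- No voxel-level analyses, no site harmonisation, no longitudinal models.
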