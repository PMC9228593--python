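# Methods

This note documents the statistical procedures implemented in
`twowave`, the assumptions behind them, and the design choices made
where the methodology left genuine latitude.

## Trajectory classification

Each child contributes three bounded symptom totals per wave: PTSD
(default 17 items scored 0–3, total 0–51), depression (10 items 0–3,
total 0–30) and externalising problems (22 items 0–2, total 0–44).
Clinical cut-offs default to 12, 10 and 12 on the adjusted totals.
Item counts are configurable because only the scale maxima and
cut-offs are fixed by the instruments' adapted versions; the defaults
are the factorisations consistent with those maxima.

**Cut-off convention.** "Scoring above the cut-off" is implemented as
`total >= cutoff`, so the printed cut-off itself flags a case. The
instruments' exact convention is not documented; the comparison is
configurable, and every classification result in the test-suite
fixtures is insensitive to the choice because fixture totals avoid the
boundary.

**Risk status.** High risk at a wave means at least one scale is at or
above its cut-off; low risk means all three are below.

**Meaningful change.** A status flip between waves only produces an
`improving` or `deteriorating` label when it is paired with a relative
change of at least 20% of the baseline total on the *relevant* scales —
every scale that was above its cut-off at baseline (for improvement)
or newly above at follow-up (for deterioration). Children whose flip
lacks the 20% change keep their baseline label (SHR or SLR), which
stops reporting noise around the cut-offs from counting as categorical
change. Two conventions were open:

* *Denominator.* Percent change is `|w2 − w1| / w1` on the scale
  total, i.e. relative to baseline. A scale-range denominator is
  available as an alternative but relative-to-baseline is the natural
  reading of "a change of at least 20%".
* *Degenerate baseline.* When a scale rises from a baseline total of
  zero to above its cut-off, the relative change is undefined; the
  package treats it as meaningful (crossing from zero is unambiguous
  worsening). The reverse case cannot occur (a zero total cannot be
  above a cut-off).
* *All vs any.* The 20% rule is required on **every** relevant scale
  by default ("cut-off(s)" being plural in the defining rule);
  `require_all_relevant=False` switches to the any-scale reading.

The classifier is validated against a literal rule-by-rule enumeration
on 1000 random small cohorts, and the four labels provably partition
any cohort.

## Symptom composite

The continuous severity index is the mean of the three per-item scale
scores (each total divided by its item count). It weights the three
domains equally on the per-item metric regardless of scale length.

## ANCOVA battery

For each predictor and mode (baseline score controlling for change,
or change score controlling for baseline), the full model is

    score ~ group dummies + companion score + age + gender
            + time since leaving + war events

and the null model drops the group dummies. The group effect is the
increment F test `F = ((RSS₀ − RSS₁)/3) / (RSS₁/df₁)`; adjusted R² is
reported from the full model. Adjusted group means are model
predictions at the sample means of the companion score and covariates.
Post-hoc contrasts are Tukey–Kramer: each pairwise difference of
adjusted means divided by its standard error, referred to the
studentized-range distribution with four groups at the residual df
(for two groups this reduces exactly to the two-sided t-test). The
Benjamini–Hochberg step-up correction is applied across the entire
battery (predictors × modes), since that is the family of models
tested in a run; the family membership is recorded in the run log.

With multiply imputed data every model is fitted per completed copy.
Scalar quantities (adjusted means, pairwise contrasts) are pooled by
Rubin's rules; the group-effect F is the multivariate Wald (D1)
statistic on the pooled coefficient vector with the
Li–Meng–Raghunathan–Rubin reference df. Pooling via Wald rather than
median-p was an open choice; Wald is the mainstream recommendation and
reduces to the complete-data F when the between-imputation variance
vanishes.

## Cross-lagged panel models

The two-wave panel model for symptom composite S and predictor P
estimates the six focal parameters a (S₁→S₂), b (P₁→P₂), c (wave-1
covariance), d (wave-2 residual covariance), e (P₁→S₂), f (S₁→P₂),
with the four covariates given paths to all four focal variables and
unconstrained mutual covariances.

* **Estimation** is equation-wise least squares: S₂ on
  (S₁, P₁, covariates) and P₂ on (P₁, S₁, covariates); c is the
  correlation of the covariate-residualized wave-1 variables and d the
  correlation of the two wave-2 regression residuals. For a
  just-identified (saturated) path model these estimates coincide with
  full-information maximum likelihood; the test suite enforces this
  with an independent numerical ML fit of the same diagram (normal
  theory discrepancy minimised over all ten free parameters),
  agreeing to a relative tolerance of 1e-4 on twenty replicate
  datasets.
* **Standardization** happens before fitting: all focal variables and
  continuous covariates are z-scored over the analysis sample so
  coefficients are standardized β; binary gender keeps its 0/1 coding.
  Whether covariates should also be standardized was open — the
  choice does not affect the focal paths, only the covariate
  coefficients' scale.
* **Saturation check.** Because a saturated model has no fit indices,
  the check is that the path-traced implied covariance of
  (S₁, P₁, S₂, P₂) — blocks V₁, V₁Bᵀ, BV₁Bᵀ+Ψ with
  B = [[a, e], [f, b]] — reproduces the sample covariance of the
  covariate-residualized variables to numerical precision.
* **Pooling** across imputations is path-wise by Rubin's rules with
  p-values from large-sample normal theory on the pooled estimates,
  matching the convention of reporting two-decimal β with significance
  stars.
* Wave-1 focal variables are regressed on the covariates (not merely
  correlated); this was flagged configurable in principle but the
  regression formulation is what the residualized c estimate and the
  saturation identity assume.

## Multiple imputation

Missing values are assumed to occur in predictors only; demographics,
war exposure and the child symptom scales must be complete and are
never altered. Imputation is fully conditional specification: each
incomplete variable is regressed on all other numeric analysis
variables; continuous/ordinal variables are imputed by type-1
predictive mean matching (Bayesian draw of the regression parameters,
then a random donor among the k=5 observed cases with closest
predicted means), binaries by a logistic parameter draw. The visit
sequence is ascending missingness fraction. Defaults are m=20
completed copies and 10 sweeps per copy; these are conventional
values — the appropriate m grows with the missing-information
fraction, and both are configurable. PMM was chosen over normal draws
because it preserves the bounded, discrete nature of questionnaire
scores without post-hoc clipping.

Rubin pooling uses T = W + (1 + 1/m)B and the Barnard–Rubin
small-sample df when a complete-data df is supplied (Rubin's
large-sample formula otherwise); B = 0 degenerates cleanly to the
complete-data analysis. Calibration is verified by a coverage
experiment: 95% pooled intervals for a known regression slope under
10% MCAR missingness cover the truth at the nominal rate over 50
replicates.

## Synthetic cohort generator

The generator draws the focal predictor and the symptom composite as
standardized latent variables following the cross-lagged structure
exactly: wave-1 scores are covariate loadings plus correlated
residuals; wave-2 scores are the structural paths plus residuals
scaled so every focal variable has unit sample variance (a systematic
variance ≥ 1 raises a configuration error naming the offending
parameters). Latents are then mapped to observables:

* The three scale totals are affine maps of the symptom latent plus a
  per-scale deviation (sd 0.3 by default), rounded and clipped to each
  integer range. Scale means are placed so baseline/follow-up
  above-cut-off rates approximate a severely exposed cohort improving
  over one year (≈55→34% PTSD, 38→27% depression, 44→42%
  externalising), and the composite computed from the totals tracks
  the latent with reliability ≈ 0.97.
* Covariates match the cohort descriptives: age truncated-normal
  11.22 ± 2.34 on 8–16; 52.9% girls; time since displacement
  truncated-normal with ~42% within three years; war events rounded
  normal 9.57 ± 5.47 clipped to 0–25.
* Non-focal predictors are AR(1) latent pairs (stability 0.4) mapped
  to Likert-like ranges; they carry no cross-lagged structure.

Default effect sizes are a = b = 0.5, e = 0.10, f = 0, c = 0.3,
d = 0.2 — a moderately stable system with a small predictor→symptom
effect, the regime the recovery experiments target. Rounding and
floor-clipping attenuate cross-wave associations by a few percent
while measurement error in the controlled wave-1 variable biases the
cross-lag slightly upward; the two effects roughly cancel, and the
Monte-Carlo recovery experiment (200 replicates at n=982) shows the
mean estimated e within ±0.005 of the generating 0.10.

What the generator does **not** emulate: item-level response
processes, attrition between waves, informative (MNAR) missingness,
floor/ceiling-induced skew beyond clipping, and reporting effects
(shared method variance between caregiver-reported scales). Passing
recovery and calibration tests therefore demonstrates correctness of
the estimators under a faithful MAR/MCAR data-generating process, not
robustness to every feature of real cohort data.

**Amputation.** MCAR deletes predictor cells independently; MAR makes
the deletion probability logistic in one observed covariate
(slope 1.0 on the standardized conditioner) with the intercept
root-solved so the expected overall fraction equals the requested
rate.

**Fixtures.** Deterministic fixtures bypass the stochastic path and
set scale totals directly (e.g. PTSD 20→8 for improving, 8→20 for
deteriorating), so the classifier reproduces any requested group
counts exactly — property-tested over random count vectors.

## Problem sizes and numerical choices

The validation experiments use: 20 datasets at n=500 for the SEM
oracle (tolerance 1e-4 relative), 200 replicates at n=982 for
cross-lag recovery and for the ANCOVA null calibration (rejection
rate compared with the binomial 95% band around 0.05), 50 replicates
at n=400 (m=10, 5 sweeps) for imputation coverage, and 1000 random
cohorts of up to 50 children for the classifier oracle. These sizes
give Monte-Carlo error comfortably below the tolerances being checked
while keeping a full validation run around a quarter of a minute.

Degenerate inputs are rejected with named errors: out-of-range
totals, empty trajectory groups, constant covariates, rank-deficient
designs, incomplete excluded variables, fewer than 10 observed values
on an incomplete variable, and n not exceeding the CLPM parameter
count. Fisher-z normal theory supplies standard errors for the two
covariance paths (c, d). Ties in the PMM donor distance are broken by
`argpartition` order, which is deterministic for a fixed seed.

## Known limitations

* The trajectory rules are sensitive to the cut-off convention at the
  boundary (a total exactly at the cut-off); both conventions are one
  flag apart.
* The CLPM is the classical two-wave model: it conflates
  between-person stability with within-person carry-over, and two
  waves cannot identify a random-intercept variant.
* The D1 pooled F for the ANCOVA battery assumes equal
  fractions of missing information across the group contrasts.
* PMM with a small donor pool can understate imputation uncertainty
  when the observed support is sparse near the predicted mean.
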