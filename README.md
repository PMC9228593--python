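# twowave

Analysis toolkit for two-wave child mental-health cohorts in
humanitarian settings: who stays at risk, who recovers, who
deteriorates — and which individual, family and community factors drive
symptoms over time (or are driven by them).

The package was built around a design used in refugee-child cohort
research: child–caregiver dyads are interviewed twice, one year apart,
with three bounded symptom scales (PTSD, depression, externalising
problems), ~20 psychosocial predictors and four covariates (age,
gender, time since displacement, war-event count). Because such cohort
data are typically not publicly deposited, `twowave` ships a synthetic
cohort generator with known ground truth, so every stage of the
pipeline can be validated end to end.

## What it computes

1. **Trajectory classification.** At each wave a child is *high risk*
   if any scale total reaches its clinical cut-off (defaults 12/51
   PTSD, 10/30 depression, 12/44 externalising), *low risk* if all
   three fall below. Across waves, children are classed as stable high
   risk (SHR), improving, deteriorating, or stable low risk (SLR); a
   status flip only counts when every scale crossing its cut-off also
   changed by at least 20% of its baseline total.
2. **Covariate-adjusted group comparisons.** For each predictor, an
   ANCOVA compares the four groups on the baseline score (controlling
   for the change score) and on the change score (controlling for
   baseline), always adjusting for the four covariates. The group
   effect is `F = ((RSS₀ − RSS₁)/3) / (RSS₁/df₁)` against the
   covariate-only null; post-hoc contrasts are Tukey–Kramer tests on
   the covariate-adjusted means, and Benjamini–Hochberg correction is
   applied across the whole battery of models.
3. **Cross-lagged panel models.** For the continuous symptom composite
   S (mean of the per-item scale scores) and a predictor P, the
   just-identified two-wave path model estimates standardized paths
   a (S₁→S₂), b (P₁→P₂), c (wave-1 covariance), d (wave-2 residual
   covariance), e (P₁→S₂) and f (S₁→P₂), with covariates on all four
   focal variables. Estimation is equation-wise least squares, which
   coincides with maximum-likelihood path analysis for a saturated
   model; the implied covariance reproducing the sample covariance is
   the model check.
4. **Multiple imputation.** Missing predictor values (demographics,
   war exposure and symptom scales are assumed complete) are imputed
   by fully conditional specification with predictive mean matching,
   and downstream estimates are pooled by Rubin's rules with
   Barnard–Rubin degrees of freedom.

## Worked example

```python
import twowave as tw

# deterministic fixture realising a known transition table
df = tw.generate_fixture_transitions((553, 238, 101, 90))
summary = tw.summarize_transitions(tw.classify_cohort(df)["trajectory"])
print(summary.to_frame().round(1))
```

```
               count  pct_total  pct_of_baseline_stratum
SHR              553       56.3                     69.9
deteriorating    101       10.3                     52.9
improving        238       24.2                     30.1
SLR               90        9.2                     47.1
```

Of 791 baseline high-risk children, 69.9% stayed high risk and 30.1%
meaningfully improved; of 191 baseline low-risk children, 52.9%
deteriorated. The follow-up low-risk share is
`summary.followup_low_pct` → `33.4`.

A stochastic cohort with a known cross-lagged effect, and its panel
model:

```python
cfg = tw.CohortConfig(seed=123)         # n=982, e=0.10 by default
data = tw.add_composite(tw.generate_cohort(cfg))
res = tw.fit_clpm(data, "self_esteem")
print(res.summary())
```

```
Cross-lagged panel model: symptom composite x self_esteem
  n = 982, standardized = True
  path   beta      se       p
     a   0.438  0.030  0.0000 ***
     b   0.534  0.029  0.0000 ***
     c   0.321  0.029  0.0000 ***
     d   0.175  0.031  0.0000 ***
     e   0.104  0.029  0.0004 ***
     f  -0.031  0.030  0.2992
```

The estimated predictor→symptom path (e = 0.104 here) recovers the
generating value 0.10 up to sampling noise; averaged over 200 replicate
cohorts the mean estimate is 0.100–0.105.

Welch's t from printed summary statistics (high-risk wellbeing
65.47 ± 26.95, n=791, vs low-risk 74.79 ± 19.44, n=191):

```python
tw.welch_t(65.47, 26.95, 791, 74.79, 19.44, 191)
# WelchResult(statistic=-5.476, df=387.2, pvalue=7.8e-08, cohens_d=-0.363)
```

## Command line

```bash
twowave all --config examples/cohort.yaml --seed 1 --out run1/
```

runs generate/ingest → classify → compare → panel models, writing
`cohort.csv`, `classification.csv`, `transitions.csv`,
`ancova_table.csv`, `clpm_table.csv`, a run log and a manifest with
config hash and file digests; identical configs give identical
analytic outputs.

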