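# Full-pipeline run on a simulated cohort under the default study
# conditions; swap `simulate:` for `input_csv: path/to/cohort.csv`
# to analyse real wide-format data.
seed: 1

simulate:
  n_dyads: 982
  missing_rate: 0.05
  focal_predictor: self_esteem
  effects:
    stability_symptom: 0.5
    stability_predictor: 0.5
    crosslag_pred_to_symptom: 0.10
    crosslag_symptom_to_pred: 0.0
    within_time_correlation_w1: 0.3
    residual_correlation_w2: 0.2

classify:
  cutoffs: [12, 10, 12]
  change_threshold: 0.20
  require_all_relevant: true

impute:
  enabled: true
  m: 20
  n_iterations: 10

compare:
  alpha: 0.05

# restrict to a predictor subset to speed a run up; omit to analyse all
predictors: [self_esteem, maternal_acceptance, caregiver_depression]
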