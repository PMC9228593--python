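"""Synthetic cohort generator: reproducibility, moments, missingness
machinery and deterministic fixtures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import statsmodels.api as sm

from twowave.config import CohortConfig, ConfigurationError, EffectSpec
from twowave.scoring import classify_cohort
from twowave.simulate import (
    amputate,
    generate_cohort,
    generate_fixture_transitions,
    predictor_columns,
)


def implied_correlations(spec: EffectSpec) -> dict[str, float]:
    """Hand path-tracing of the cross-wave correlations (no covariates)."""
    a, b = spec.stability_symptom, spec.stability_predictor
    e, f = spec.crosslag_pred_to_symptom, spec.crosslag_symptom_to_pred
    c = spec.within_time_correlation_w1
    return {
        ("symptom_w1", "predictor_w1"): c,
        ("symptom_w1", "symptom_w2"): a + e * c,
        ("symptom_w1", "predictor_w2"): f + b * c,
        ("predictor_w1", "symptom_w2"): e + a * c,
        ("predictor_w1", "predictor_w2"): b + f * c,
    }


def _no_covariate_effects():
    zero = {k: {c: 0.0 for c in ("age", "gender", "time_since_leaving",
                                 "war_events")}
            for k in ("symptom_w1", "symptom_w2", "predictor_w1",
                      "predictor_w2")}
    return zero


class TestGenerateCohort:
    def test_same_seed_is_byte_identical(self):
        cfg = CohortConfig(n_dyads=300, seed=5, missing_rate=0.1)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        assert a.equals(b)
        assert a.to_csv() == b.to_csv()

    def test_latent_moments_match_hand_path_tracing(self):
        spec = EffectSpec(stability_symptom=0.45, stability_predictor=0.55,
                          crosslag_pred_to_symptom=0.15,
                          crosslag_symptom_to_pred=-0.10,
                          within_time_correlation_w1=0.25,
                          residual_correlation_w2=0.2,
                          covariate_loadings=_no_covariate_effects())
        cfg = CohortConfig(n_dyads=10_000, seed=2, effect_spec=spec)
        _, latent = generate_cohort(cfg, return_latent=True)
        corr = latent.corr()
        for (u, v), rho in implied_correlations(spec).items():
            assert corr.loc[u, v] == pytest.approx(rho, abs=0.03)

    def test_null_crosslag_partial_correlation_vanishes(
            self, null_crosslag_cohort):
        df = null_crosslag_cohort
        resid_s2 = sm.OLS(df["symptom_w2"],
                          sm.add_constant(df["symptom_w1"])).fit().resid
        resid_p1 = sm.OLS(df["self_esteem_w1"],
                          sm.add_constant(df["symptom_w1"])).fit().resid
        r = np.corrcoef(resid_s2, resid_p1)[0, 1]
        assert abs(r) < 0.03

    def test_no_missing_cells_at_rate_zero(self):
        df = generate_cohort(CohortConfig(n_dyads=200, seed=1))
        assert not df.isna().any().any()

    def test_scale_totals_within_bounds(self, default_cohort):
        for col, mx in (("ptsd", 51), ("dep", 30), ("ext", 44)):
            for w in (1, 2):
                vals = default_cohort[f"{col}_w{w}"]
                assert vals.between(0, mx).all()
                assert (vals == vals.astype(int)).all()

    def test_covariates_within_configured_ranges(self, default_cohort):
        assert default_cohort["age"].between(8, 16).all()
        assert set(default_cohort["gender"].unique()) <= {0, 1}
        assert default_cohort["war_events"].between(0, 25).all()

    def test_nonpositive_definite_spec_names_parameters(self):
        spec = EffectSpec(stability_symptom=0.9,
                          crosslag_pred_to_symptom=0.6,
                          within_time_correlation_w1=0.5)
        with pytest.raises(ConfigurationError, match="positive definite"):
            generate_cohort(CohortConfig(n_dyads=50, seed=0, effect_spec=spec))

    def test_correlation_outside_unit_interval_rejected(self):
        with pytest.raises(ConfigurationError,
                           match="within_time_correlation_w1"):
            EffectSpec(within_time_correlation_w1=1.2).validate()


class TestAmputate:
    def test_rate_zero_is_identity(self, default_cohort):
        assert amputate(default_cohort, 0.0).equals(default_cohort)

    def test_rate_one_rejected(self, default_cohort):
        with pytest.raises(ValueError):
            amputate(default_cohort, 1.0)

    def test_mcar_fraction_within_binomial_band(self):
        df = generate_cohort(CohortConfig(n_dyads=1000, seed=9))
        out = amputate(df, 0.1, mechanism="MCAR", seed=3)
        cols = predictor_columns(out)
        assert len(cols) == 40  # 20 predictors x 2 waves
        frac = out[cols].isna().to_numpy().mean()
        assert 0.08 <= frac <= 0.12

    def test_symptoms_and_covariates_untouched(self):
        df = generate_cohort(CohortConfig(n_dyads=500, seed=9))
        out = amputate(df, 0.3, mechanism="MCAR", seed=3)
        protected = ["age", "gender", "time_since_leaving", "war_events"]
        protected += [f"{s}_w{w}" for s in ("ptsd", "dep", "ext")
                      for w in (1, 2)]
        assert not out[protected].isna().any().any()
        assert out[protected].equals(df[protected])

    def test_mar_missingness_monotone_in_conditioning_tertiles(self):
        df = generate_cohort(CohortConfig(n_dyads=3000, seed=10))
        out = amputate(df, 0.15, mechanism="MAR", seed=4,
                       condition_on="war_events")
        cols = predictor_columns(out)
        tertile = pd.qcut(out["war_events"], 3, labels=False, duplicates="drop")
        rates = [out.loc[tertile == t, cols].isna().to_numpy().mean()
                 for t in sorted(tertile.unique())]
        assert rates == sorted(rates)
        assert rates[-1] > rates[0]
        # overall fraction still calibrated to the requested rate
        assert out[cols].isna().to_numpy().mean() == pytest.approx(0.15,
                                                                   abs=0.02)

    def test_mar_requires_conditioning_variable(self, default_cohort):
        with pytest.raises(ValueError, match="condition_on"):
            amputate(default_cohort, 0.1, mechanism="MAR", seed=0)


class TestFixtures:
    @pytest.mark.parametrize("counts", [
        (553, 238, 101, 90),
        (0, 0, 0, 5),
        (1, 1, 1, 1),
    ])
    def test_classifier_reproduces_requested_counts(self, counts):
        df = generate_fixture_transitions(counts)
        labels = classify_cohort(df)["trajectory"]
        got = labels.value_counts().reindex(
            ["SHR", "improving", "deteriorating", "SLR"], fill_value=0)
        assert tuple(got) == counts

    @given(st.tuples(st.integers(0, 30), st.integers(0, 30),
                     st.integers(0, 30), st.integers(0, 30)))
    @settings(max_examples=40, deadline=None)
    def test_fixture_soundness_property(self, counts):
        df = generate_fixture_transitions(counts)
        if sum(counts) == 0:
            assert df.empty
            return
        labels = classify_cohort(df)["trajectory"]
        got = labels.value_counts().reindex(
            ["SHR", "improving", "deteriorating", "SLR"], fill_value=0)
        assert tuple(got) == counts

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            generate_fixture_transitions((1, -1, 0, 0))
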