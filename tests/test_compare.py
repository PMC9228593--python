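"""Group comparisons: Welch t, ANOVA, chi-square, BH and the ANCOVA
model objects."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from twowave.compare import (
    Ancova,
    ancova_battery,
    bh_adjust,
    chi_square,
    oneway_anova,
    tukey_pairwise,
    welch_t,
)
from twowave.scoring import LABELS

from _oracles import normal_equations_ancova


class TestWelch:
    def test_printed_wellbeing_worked_example(self):
        """High- vs low-risk wellbeing at baseline: t(387.19) = -5.47."""
        res = welch_t(65.47, 26.95, 791, 74.79, 19.44, 191)
        assert res.statistic == pytest.approx(-5.47, abs=0.01)
        assert res.df == pytest.approx(387.19, abs=0.1)
        assert res.pvalue < 0.001

    def test_identical_groups_give_zero(self):
        res = welch_t(10, 2, 50, 10, 2, 50)
        assert res.statistic == 0.0
        assert res.cohens_d == 0.0

    def test_equal_variance_equal_n_reduces_to_pooled_df(self):
        res = welch_t(1.0, 2.0, 30, 0.0, 2.0, 30)
        assert res.df == pytest.approx(58)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            welch_t(1, 0.0, 30, 0, 1.0, 30)
        with pytest.raises(ValueError):
            welch_t(1, 1.0, 1, 0, 1.0, 30)


class TestAnovaChi2:
    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        g = np.repeat(["a", "b"], 20)
        f, (df1, df2), p_f = oneway_anova(x, g)
        t, p_t = stats.ttest_ind(x[g == "a"], x[g == "b"])
        assert f == pytest.approx(t**2)
        assert p_f == pytest.approx(p_t)

    def test_uniform_table_gives_zero_chi2(self):
        chi2, df, p = chi_square([[10, 10], [10, 10]])
        assert chi2 == 0.0
        assert p == pytest.approx(1.0)

    def test_gender_group_association_detected(self):
        # 4x2 table with a built-in association
        table = [[80, 40], [30, 60], [50, 50], [20, 55]]
        chi2, df, p = chi_square(table)
        assert df == 3
        assert p < 0.05


class TestBH:
    def test_single_p_unchanged(self):
        adj, rej = bh_adjust([0.03])
        assert adj[0] == pytest.approx(0.03)
        assert rej[0]

    def test_step_up_arithmetic(self):
        adj, _ = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_ones_reject_nothing(self):
        adj, rej = bh_adjust([1.0, 1.0, 1.0])
        assert not rej.any()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=25))
    @settings(max_examples=100, deadline=None)
    def test_adjusted_monotone_and_rejections_nest(self, pvals):
        adj, rej_05 = bh_adjust(pvals, alpha=0.05)
        order = np.argsort(pvals)
        assert (np.diff(np.asarray(adj)[order]) >= -1e-12).all()
        _, rej_10 = bh_adjust(pvals, alpha=0.10)
        assert (~rej_05 | rej_10).all()  # alpha=.05 rejections nest in .10


def _ancova_frame(rng, n=400, effect=0.0):
    groups = rng.choice(LABELS, size=n)
    w1 = rng.normal(3, 0.8, n)
    offsets = dict(zip(LABELS, [0.0, effect, 2 * effect, 3 * effect]))
    w1 = w1 + np.array([offsets[g] for g in groups])
    w2 = 0.6 * w1 + rng.normal(0, 0.6, n)
    return pd.DataFrame({
        "pred_w1": w1, "pred_w2": w2, "trajectory": groups,
        "age": rng.uniform(8, 16, n), "gender": rng.integers(0, 2, n),
        "time_since_leaving": rng.uniform(0, 8, n),
        "war_events": rng.integers(0, 26, n),
    })


class TestAncova:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        for trial in range(10):
            df = _ancova_frame(rng, n=120, effect=0.3)
            model = Ancova(df, "pred", mode="baseline")
            res = model.fit()
            y, X_full, X_null, _ = model._design(df)
            f_oracle, beta = normal_equations_ancova(y, X_full, X_null)
            assert res.fvalue == pytest.approx(f_oracle, rel=1e-8)
            assert res.group_effects == pytest.approx(beta[-3:], rel=1e-8)

    def test_f_is_zero_when_groups_add_nothing(self):
        """Outcome built as null-model fit plus a component orthogonal
        to the full design leaves the group dummies nothing to explain."""
        rng = np.random.default_rng(2)
        df = _ancova_frame(rng, n=200)
        model = Ancova(df, "pred", mode="baseline")
        y, X_full, X_null, groups = model._design(df)
        import statsmodels.api as sm
        full = sm.OLS(y, X_full).fit()
        null = sm.OLS(y, X_null).fit()
        y_star = null.fittedvalues + full.resid
        df2 = df.copy()
        df2["pred_w1"] = y_star  # change score shifts too; rebuild w2
        df2["pred_w2"] = y_star + (df["pred_w2"] - df["pred_w1"])
        res = Ancova(df2, "pred", mode="baseline").fit()
        assert res.fvalue == pytest.approx(0.0, abs=1e-6)

    def test_one_sd_group_offsets_detected(self):
        rng = np.random.default_rng(3)
        df = _ancova_frame(rng, n=982, effect=0.8)  # 1 SD steps
        res = Ancova(df, "pred", mode="baseline").fit()
        assert res.pvalue < 0.001
        assert res.df[0] == 3

    def test_change_mode_controls_for_baseline(self):
        rng = np.random.default_rng(4)
        df = _ancova_frame(rng, n=300)
        res = Ancova(df, "pred", mode="change").fit()
        assert res.mode == "change"
        assert res.fvalue >= 0

    def test_empty_group_is_named_in_error(self):
        rng = np.random.default_rng(5)
        df = _ancova_frame(rng, n=100)
        df = df[df["trajectory"] != "SLR"]
        with pytest.raises(ValueError, match="SLR"):
            Ancova(df, "pred").fit()

    def test_constant_covariate_is_named_in_error(self):
        rng = np.random.default_rng(6)
        df = _ancova_frame(rng, n=100)
        df["war_events"] = 5
        with pytest.raises(ValueError, match="war_events"):
            Ancova(df, "pred").fit()

    def test_adjusted_means_at_covariate_means(self):
        """With zero group effects forced, adjusted means all equal the
        prediction at the covariate means."""
        rng = np.random.default_rng(7)
        df = _ancova_frame(rng, n=500, effect=0.0)
        res = Ancova(df, "pred").fit()
        spread = res.adjusted_means.max() - res.adjusted_means.min()
        assert spread < 0.3  # no systematic separation under the null


class TestTukey:
    def test_two_groups_reduce_to_t_test(self):
        means = pd.Series({"a": 0.0, "b": 0.5})
        se2 = 0.04  # variance of the difference
        cov = np.array([[se2]])
        df_resid = 60
        out = tukey_pairwise(means, cov, df_resid)
        t = 0.5 / np.sqrt(se2)
        p_t = 2 * stats.t.sf(abs(t), df_resid)
        assert out.loc[0, "pvalue"] == pytest.approx(p_t, rel=1e-6)

    def test_identical_means_not_significant(self):
        rng = np.random.default_rng(8)
        df = _ancova_frame(rng, n=800, effect=0.0)
        out = Ancova(df, "pred").fit().tukey()
        assert len(out) == 6
        assert (out["pvalue"] > 0.05).all() or (out["pvalue"] > 0.01).all()

    def test_offset_group_flagged(self):
        rng = np.random.default_rng(9)
        df = _ancova_frame(rng, n=2000, effect=0.0)
        df.loc[df["trajectory"] == "SLR", "pred_w1"] += 0.5
        out = Ancova(df, "pred").fit().tukey()
        slr = out[(out["group1"] == "SLR") | (out["group2"] == "SLR")]
        rest = out[(out["group1"] != "SLR") & (out["group2"] != "SLR")]
        assert (slr["pvalue"] < 0.05).all()
        assert (rest["pvalue"] > 0.05).all()


class TestBattery:
    def test_bh_family_spans_all_models(self):
        rng = np.random.default_rng(10)
        df = _ancova_frame(rng, n=300)
        df = df.rename(columns={"pred_w1": "p1_w1", "pred_w2": "p1_w2"})
        df["p2_w1"] = rng.normal(size=len(df))
        df["p2_w2"] = rng.normal(size=len(df))
        table, results = ancova_battery(df, ["p1", "p2"])
        assert len(table) == 4  # 2 predictors x 2 modes
        assert table["p_bh"].notna().all()
        adj, _ = bh_adjust(table["p"])
        assert table["p_bh"].to_numpy() == pytest.approx(adj)
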