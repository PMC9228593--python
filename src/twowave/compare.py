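"""Covariate-adjusted group comparisons.

The centrepiece is :class:`Ancova`, a statsmodels-style model object:
for one predictor it regresses either the baseline score (controlling
for the change score) or the change score (controlling for baseline) on
the four trajectory groups plus the demographic covariates, and reports
the group effect as an F test of the full model against the
covariate-only null.  Post-hoc contrasts are Tukey--Kramer comparisons
of the covariate-adjusted group means.  :func:`ancova_battery` runs the
whole battery of (predictor x mode) models and applies the
Benjamini--Hochberg correction across all of them.

Descriptive helpers (:func:`welch_t`, :func:`oneway_anova`,
:func:`chi_square`) cover the unadjusted two- and four-group tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.stats import studentized_range
from statsmodels.stats.multitest import multipletests

from .config import COVARIATE_NAMES
from .impute import ImputedDatasets, rubin_pool
from .scoring import LABELS

__all__ = ["Ancova", "AncovaResults", "ancova_battery", "bh_adjust",
           "welch_t", "oneway_anova", "chi_square", "WelchResult",
           "tukey_pairwise"]


class WelchResult(NamedTuple):
    statistic: float
    df: float
    pvalue: float
    cohens_d: float


def welch_t(mean1, sd1, n1, mean2, sd2, n2) -> WelchResult:
    """Welch's two-sample t-test from summary statistics.

    The statistic is (mean1 - mean2) / se with Welch--Satterthwaite
    degrees of freedom; Cohen's d uses the pooled standard deviation.
    """
    n1, n2 = int(n1), int(n2)
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    se = np.sqrt(v1 + v2)
    t = (mean1 - mean2) / se
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2 * stats.t.sf(abs(t), df)
    sd_pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    d = (mean1 - mean2) / sd_pooled
    return WelchResult(float(t), float(df), float(p), float(d))


def oneway_anova(values, groups):
    """One-way ANOVA; returns (F, (df_between, df_within), p)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in pd.unique(groups)]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    f, p = stats.f_oneway(*samples)
    df1 = len(samples) - 1
    df2 = len(values) - len(samples)
    return float(f), (df1, df2), float(p)


def chi_square(table):
    """Pearson chi-square on a contingency table, no continuity
    correction; returns (chi2, df, p)."""
    res = stats.chi2_contingency(np.asarray(table), correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def bh_adjust(pvalues, alpha: float = 0.05):
    """Benjamini--Hochberg step-up FDR adjustment.

    Returns (adjusted p-values, rejection flags at ``alpha``); the
    adjusted values are monotone in the raw ordering.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject


# ---------------------------------------------------------------------------


def tukey_pairwise(means: pd.Series, effect_cov: np.ndarray,
                   df_resid: float) -> pd.DataFrame:
    """Tukey--Kramer pairwise comparisons of (adjusted) group means.

    ``effect_cov`` is the covariance matrix of the treatment-coded group
    coefficients (reference = first label of ``means``); p-values come
    from the studentized range with ``len(means)`` groups at the
    residual df, which for two groups reduces to the two-sided t-test
    via q = t * sqrt(2).
    """
    labels = list(means.index)
    k = len(labels)
    # map k-1 treatment effects to per-group rows (reference row = 0)
    full = np.vstack([np.zeros(k - 1), np.eye(k - 1)])
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            contrast = full[j] - full[i]
            diff = float(means.iloc[j] - means.iloc[i])
            se = float(np.sqrt(contrast @ effect_cov @ contrast))
            if se == 0:
                q = 0.0 if diff == 0 else np.inf
            else:
                q = abs(diff) * np.sqrt(2) / se
            p = float(studentized_range.sf(q, k, df_resid))
            crit = studentized_range.ppf(0.95, k, df_resid) / np.sqrt(2)
            rows.append({
                "group1": labels[i], "group2": labels[j],
                "diff": diff, "se": se,
                "lower": diff - crit * se, "upper": diff + crit * se,
                "pvalue": min(1.0, p),
            })
    return pd.DataFrame(rows)


@dataclass
class AncovaResults:
    """Fitted ANCOVA for one predictor in one mode."""

    predictor: str
    mode: str                      # "baseline" | "change"
    fvalue: float
    df: tuple[int, float]          # (numerator, residual)
    pvalue: float
    rsquared_adj: float
    adjusted_means: pd.Series      # covariate-adjusted means by group
    group_effects: np.ndarray      # treatment-coded group coefficients
    group_cov: np.ndarray          # their covariance matrix
    nobs: int
    pvalue_bh: float | None = None
    pooled: bool = False

    def tukey(self) -> pd.DataFrame:
        """Tukey--Kramer comparisons of the adjusted group means.

        All six pairwise differences, with studentized-range p-values at
        the residual df and 95% simultaneous intervals.
        """
        return tukey_pairwise(self.adjusted_means, self.group_cov, self.df[1])

    def summary(self) -> str:
        lines = [
            f"ANCOVA: {self.predictor} ({self.mode} mode"
            + (", pooled over imputations)" if self.pooled else ")"),
            f"  n = {self.nobs}",
            f"  F({self.df[0]}, {self.df[1]:.1f}) = {self.fvalue:.3f}, "
            f"p = {self.pvalue:.4g}"
            + (f", BH-adjusted p = {self.pvalue_bh:.4g}"
               if self.pvalue_bh is not None else ""),
            f"  adjusted R^2 (full model) = {self.rsquared_adj:.3f}",
            "  adjusted group means:",
        ]
        for g, mval in self.adjusted_means.items():
            lines.append(f"    {g:>13s}: {mval:.3f}")
        return "\n".join(lines)


class Ancova:
    """ANCOVA of one predictor across the four trajectory groups.

    Parameters
    ----------
    data
        Wide cohort frame including a ``trajectory`` label column.
    predictor
        Predictor base name; ``<predictor>_w1`` and ``_w2`` must exist.
    mode
        ``"baseline"`` models the w1 score controlling for the change
        score; ``"change"`` models w2-w1 controlling for the baseline.
    covariates
        Additional adjustment variables present in ``data``.
    """

    def __init__(self, data: pd.DataFrame, predictor: str,
                 group_col: str = "trajectory",
                 covariates: Sequence[str] = COVARIATE_NAMES,
                 mode: str = "baseline"):
        if mode not in ("baseline", "change"):
            raise ValueError("mode must be 'baseline' or 'change'")
        self.predictor = predictor
        self.mode = mode
        self.group_col = group_col
        self.covariates = tuple(covariates)
        self.data = data

    # -- design construction -------------------------------------------------

    def _design(self, data: pd.DataFrame):
        w1 = data[f"{self.predictor}_w1"].to_numpy(dtype=float)
        w2 = data[f"{self.predictor}_w2"].to_numpy(dtype=float)
        change = w2 - w1
        y, companion = (w1, change) if self.mode == "baseline" else (change, w1)

        groups = data[self.group_col].astype(str)
        bad = set(groups.unique()) - set(LABELS)
        if bad:
            raise ValueError(f"unknown trajectory labels {sorted(bad)}")
        counts = groups.value_counts().reindex(LABELS, fill_value=0)
        empty = counts[counts == 0].index.tolist()
        if empty:
            raise ValueError(f"singular design: empty group(s) {empty}")

        dummies = np.column_stack([(groups == g).astype(float)
                                   for g in LABELS[1:]])
        cov_arrays = []
        for c in self.covariates:
            arr = data[c].to_numpy(dtype=float)
            if np.ptp(arr) == 0:
                raise ValueError(f"singular design: covariate {c!r} is constant")
            cov_arrays.append(arr)
        controls = np.column_stack([companion, *cov_arrays]) if cov_arrays \
            else companion[:, None]
        X_null = np.column_stack([np.ones(len(y)), controls])
        X_full = np.column_stack([X_null, dummies])
        return y, X_full, X_null, groups

    def fit(self) -> AncovaResults:
        y, X_full, X_null, groups = self._design(self.data)
        full = sm.OLS(y, X_full).fit()
        null = sm.OLS(y, X_null).fit()
        k_groups = len(LABELS) - 1
        df_resid = full.df_resid
        rss_full, rss_null = full.ssr, null.ssr
        f = ((rss_null - rss_full) / k_groups) / (rss_full / df_resid)
        p = float(stats.f.sf(f, k_groups, df_resid))

        idx = np.arange(X_full.shape[1] - k_groups, X_full.shape[1])
        effects = full.params[idx]
        cov = full.cov_params()[np.ix_(idx, idx)]
        adj = self._adjusted_means(full.params, X_full, groups)
        return AncovaResults(
            predictor=self.predictor, mode=self.mode,
            fvalue=float(f), df=(k_groups, float(df_resid)), pvalue=p,
            rsquared_adj=float(full.rsquared_adj),
            adjusted_means=adj, group_effects=np.asarray(effects),
            group_cov=np.asarray(cov), nobs=int(full.nobs),
        )

    def _adjusted_means(self, params, X_full, groups) -> pd.Series:
        """Predicted outcome per group at the sample means of the
        companion score and covariates."""
        k_groups = len(LABELS) - 1
        base = X_full[:, : X_full.shape[1] - k_groups].mean(axis=0)
        means = {}
        for g_idx, g in enumerate(LABELS):
            row = np.concatenate([base, np.zeros(k_groups)])
            if g_idx > 0:
                row[X_full.shape[1] - k_groups + g_idx - 1] = 1.0
            means[g] = float(row @ params)
        return pd.Series(means)

    # -- multiple imputation -------------------------------------------------

    def fit_pooled(self, imputed: ImputedDatasets,
                   classify_kwargs: dict | None = None) -> AncovaResults:
        """Fit on every completed copy and pool.

        Group coefficients and adjusted means are pooled by Rubin's
        rules; the group-effect F is the multivariate Wald (D1)
        statistic on the pooled coefficient vector.
        """
        fits = []
        for d in imputed:
            model = Ancova(d, self.predictor, self.group_col,
                           self.covariates, self.mode)
            fits.append(model.fit())
        m = len(fits)
        k = len(fits[0].group_effects)
        Q = np.vstack([f.group_effects for f in fits])
        U = np.mean([f.group_cov for f in fits], axis=0)
        qbar = Q.mean(axis=0)
        B = np.cov(Q.T, ddof=1) if m > 1 else np.zeros((k, k))
        r = (1 + 1 / m) * np.trace(B @ np.linalg.pinv(U)) / k
        d1 = float(qbar @ np.linalg.pinv(U) @ qbar) / (k * (1 + r))
        # Li, Meng, Raghunathan & Rubin reference df
        t_df = k * (m - 1)
        if t_df > 4:
            df2 = 4 + (t_df - 4) * (1 + (1 - 2 / t_df) / r) ** 2 if r > 0 \
                else np.inf
        else:
            df2 = t_df * (1 + 1 / k) * (1 + 1 / r) ** 2 / 2 if r > 0 else np.inf
        p = float(stats.f.sf(d1, k, df2)) if np.isfinite(df2) \
            else float(stats.chi2.sf(d1 * k, k))

        adj = pd.DataFrame([f.adjusted_means for f in fits]).mean()
        cov_total = U * (1 + r)
        res_df = float(np.mean([f.df[1] for f in fits]))
        return AncovaResults(
            predictor=self.predictor, mode=self.mode,
            fvalue=d1, df=(k, res_df), pvalue=p,
            rsquared_adj=float(np.mean([f.rsquared_adj for f in fits])),
            adjusted_means=adj, group_effects=qbar, group_cov=cov_total,
            nobs=fits[0].nobs, pooled=True,
        )


def ancova_battery(data, predictors: Sequence[str],
                   group_col: str = "trajectory",
                   covariates: Sequence[str] = COVARIATE_NAMES,
                   modes: Sequence[str] = ("baseline", "change"),
                   alpha: float = 0.05) -> tuple[pd.DataFrame, list[AncovaResults]]:
    """Run the full ANCOVA battery and BH-correct across all models.

    ``data`` may be a single complete DataFrame or an
    :class:`ImputedDatasets`, in which case every model is fitted per
    copy and pooled.  The BH family is the whole battery
    (predictors x modes), matching a correction for the total number of
    models tested.
    """
    results: list[AncovaResults] = []
    for predictor in predictors:
        for mode in modes:
            if isinstance(data, ImputedDatasets):
                model = Ancova(data.datasets[0], predictor, group_col,
                               covariates, mode)
                results.append(model.fit_pooled(data))
            else:
                model = Ancova(data, predictor, group_col, covariates, mode)
                results.append(model.fit())
    p_adj, reject = bh_adjust([r.pvalue for r in results], alpha)
    rows = []
    for res, pa, rej in zip(results, p_adj, reject):
        res.pvalue_bh = float(pa)
        row = {"predictor": res.predictor, "mode": res.mode,
               "F": res.fvalue, "df1": res.df[0], "df2": res.df[1],
               "p": res.pvalue, "p_bh": res.pvalue_bh, "significant": bool(rej),
               "adj_r2": res.rsquared_adj, "n": res.nobs}
        for g, mval in res.adjusted_means.items():
            row[f"adj_mean_{g}"] = mval
        rows.append(row)
    return pd.DataFrame(rows), results
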