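"""Fully conditional specification (chained-equations) multiple
imputation and Rubin's-rules pooling.

Each incomplete predictor is imputed from a linear model on all other
analysis variables.  Continuous/ordinal variables use predictive mean
matching (PMM, type-1 matching with k donors) after a Bayesian draw of
the regression parameters, which keeps imputed values on the observed
scale without clipping; binary variables use a logistic parameter draw.
The m chains are independent and the whole procedure is deterministic
under a fixed seed.  Variables excluded from imputation (demographics,
war exposure, child symptom scales) must be fully observed and are
never altered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, t as t_dist

from .config import COVARIATE_NAMES, SCALE_NAMES

__all__ = ["ImputedDatasets", "PooledEstimate", "fcs_impute", "rubin_pool",
           "default_exclude"]


def default_exclude() -> tuple[str, ...]:
    """Columns never imputed: id, demographics, war exposure and the
    child symptom scales (these must be fully observed)."""
    scales = tuple(f"{s}_w{w}" for s in SCALE_NAMES for w in (1, 2))
    return ("dyad_id", *COVARIATE_NAMES, *scales, "symptom_w1", "symptom_w2")


@dataclass
class ImputedDatasets:
    """m completed copies of one incomplete dataset."""

    datasets: list[pd.DataFrame]
    seed: int
    n_iterations: int
    methods: dict[str, str] = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.datasets)

    def __iter__(self):
        return iter(self.datasets)

    def to_csv(self, directory, prefix: str = "imputed") -> list[str]:
        """Serialise the copies plus a manifest for audit."""
        import json
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for i, d in enumerate(self.datasets, start=1):
            p = directory / f"{prefix}_{i:02d}.csv"
            d.to_csv(p, index=False)
            paths.append(str(p))
        manifest = {"m": self.m, "seed": self.seed,
                    "n_iterations": self.n_iterations, "methods": self.methods,
                    "files": paths}
        (directory / f"{prefix}_manifest.json").write_text(
            json.dumps(manifest, indent=2))
        return paths


def _is_binary(values: np.ndarray) -> bool:
    u = np.unique(values[~np.isnan(values)])
    return len(u) <= 2


def _mvn_draw(mean, cov, rng):
    """Multivariate normal draw via eigen-clipping, tolerant of the
    slight asymmetry/indefiniteness pinv can leave behind."""
    cov = (cov + cov.T) / 2
    vals, vecs = np.linalg.eigh(cov)
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    return mean + root @ rng.standard_normal(len(mean))


def _bayes_ols_draw(X, y, rng):
    """Posterior draw (sigma2*, beta*) under the standard noninformative
    prior for the normal linear model."""
    n, k = X.shape
    beta_hat, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_hat
    dof = max(n - k, 1)
    s2 = float(resid @ resid) / dof
    sigma2 = s2 * dof / chi2.rvs(dof, random_state=rng)
    XtX_inv = np.linalg.pinv(X.T @ X)
    beta_star = _mvn_draw(beta_hat, sigma2 * XtX_inv, rng)
    return beta_hat, beta_star


def _pmm_draw(X_obs, y_obs, X_mis, rng, k_donors=5):
    """Type-1 predictive mean matching."""
    beta_hat, beta_star = _bayes_ols_draw(X_obs, y_obs, rng)
    yhat_obs = X_obs @ beta_hat
    yhat_mis = X_mis @ beta_star
    out = np.empty(len(yhat_mis))
    for j, target in enumerate(yhat_mis):
        dist = np.abs(yhat_obs - target)
        k = min(k_donors, len(y_obs))
        donors = np.argpartition(dist, k - 1)[:k]
        out[j] = y_obs[rng.choice(donors)]
    return out


def _logistic_draw(X_obs, y_obs, X_mis, rng):
    import statsmodels.api as sm

    values = np.unique(y_obs)
    y01 = (y_obs == values.max()).astype(float)
    try:
        fit = sm.GLM(y01, X_obs, family=sm.families.Binomial()).fit()
        beta_star = _mvn_draw(np.asarray(fit.params),
                              np.asarray(fit.cov_params()), rng)
    except Exception:  # separation etc.: fall back to marginal draw
        p = np.full(len(X_mis), y01.mean())
        return np.where(rng.random(len(X_mis)) < p,
                        values.max(), values.min())
    p = expit(X_mis @ beta_star)
    return np.where(rng.random(len(X_mis)) < p, values.max(), values.min())


def fcs_impute(df: pd.DataFrame, m: int = 20, n_iterations: int = 10,
               seed: int = 0, exclude=None, k_donors: int = 5,
               min_observed: int = 10) -> ImputedDatasets:
    """Chained-equations multiple imputation of incomplete predictors.

    Parameters
    ----------
    df
        Wide-format cohort; incomplete cells only among non-excluded
        columns.
    m, n_iterations
        Number of completed copies and FCS sweeps per copy.
    exclude
        Columns left out of the imputation model's targets; they must
        be fully observed (default: id, covariates, symptom scales).
    k_donors
        PMM donor-pool size.

    The visit sequence is ascending missingness fraction, a standard
    FCS stabiliser that also makes the sweep deterministic.
    """
    exclude = tuple(exclude) if exclude is not None else default_exclude()
    exclude = tuple(c for c in exclude if c in df.columns)
    for col in exclude:
        if df[col].isna().any():
            raise ValueError(
                f"excluded variable {col!r} has missing values; excluded "
                "variables must be fully observed")

    # non-numeric columns (e.g. trajectory labels) pass through untouched
    numeric_cols = [c for c in df.columns
                    if pd.api.types.is_numeric_dtype(df[c])]
    candidates = [c for c in numeric_cols
                  if c not in exclude and c != "dyad_id"]
    numeric = df[candidates].astype(float)
    incomplete = [c for c in candidates if numeric[c].isna().any()]
    for col in incomplete:
        n_obs = int(numeric[col].notna().sum())
        if n_obs < min_observed:
            raise ValueError(
                f"variable {col!r} has only {n_obs} observed values; "
                "widen the data or override the imputation method")

    methods = {}
    for col in incomplete:
        methods[col] = "logreg" if _is_binary(numeric[col].to_numpy()) else "pmm"

    if not incomplete:
        return ImputedDatasets([df.copy() for _ in range(m)], seed,
                               n_iterations, methods)

    # ascending missingness fraction
    incomplete.sort(key=lambda c: (numeric[c].isna().mean(), c))

    # design variables: every numeric analysis variable except the target
    design_cols = [c for c in numeric_cols if c != "dyad_id"]
    base = df[design_cols].astype(float)
    obs_mask = base.notna()

    child_seeds = np.random.SeedSequence(seed).spawn(m)
    copies = []
    for chain_seq in child_seeds:
        rng = np.random.default_rng(chain_seq)
        work = base.copy()
        # initial fill: random observed donors
        for col in incomplete:
            miss = ~obs_mask[col]
            donors = work.loc[obs_mask[col], col].to_numpy()
            work.loc[miss, col] = rng.choice(donors, size=int(miss.sum()))
        for _ in range(n_iterations):
            for col in incomplete:
                others = [c for c in design_cols if c != col]
                X = np.column_stack([np.ones(len(work)),
                                     work[others].to_numpy(dtype=float)])
                y = work[col].to_numpy(dtype=float)
                obs = obs_mask[col].to_numpy()
                if methods[col] == "pmm":
                    imputed = _pmm_draw(X[obs], y[obs], X[~obs], rng, k_donors)
                else:
                    imputed = _logistic_draw(X[obs], y[obs], X[~obs], rng)
                work.loc[~obs, col] = imputed
        out = df.copy()
        for col in incomplete:
            out[col] = work[col].to_numpy()
        copies.append(out)
    return ImputedDatasets(copies, seed, n_iterations, methods)


@dataclass(frozen=True)
class PooledEstimate:
    """One estimate combined across imputations by Rubin's rules."""

    estimate: float
    within_variance: float
    between_variance: float
    total_variance: float
    df: float
    se: float
    pvalue: float
    m: int

    def confint(self, alpha: float = 0.05) -> tuple[float, float]:
        crit = t_dist.ppf(1 - alpha / 2, self.df) if np.isfinite(self.df) \
            else 1.959963984540054
        return (self.estimate - crit * self.se, self.estimate + crit * self.se)


def rubin_pool(estimates, variances, df_complete: float | None = None,
               ) -> PooledEstimate:
    """Combine per-copy estimates and variances.

    Pooled estimate is the mean; total variance T = W + (1 + 1/m)B.
    Reference df follows Barnard--Rubin when a complete-data df is
    given, otherwise Rubin's large-sample formula; with zero
    between-imputation variance the df is infinite and the p-value
    reduces to the normal test on the common estimate.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape:
        raise ValueError("estimates and variances must have equal length")
    m = q.size
    if m < 2:
        raise ValueError("pooling requires m >= 2 imputations")
    qbar = float(q.mean())
    w = float(u.mean())
    b = float(q.var(ddof=1))
    t_var = w + (1 + 1 / m) * b

    lam = (1 + 1 / m) * b / t_var if t_var > 0 else 0.0
    if lam < 1e-12:  # effectively no between-imputation variance
        df = float("inf")
    else:
        df_old = (m - 1) / lam**2
        if df_complete is None or not np.isfinite(df_complete):
            df = df_old
        else:
            df_obs = ((df_complete + 1) / (df_complete + 3)
                      * df_complete * (1 - lam))
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)

    se = float(np.sqrt(t_var))
    if se == 0:
        p = 0.0 if qbar != 0 else 1.0
    elif np.isfinite(df):
        p = float(2 * t_dist.sf(abs(qbar) / se, df))
    else:
        from scipy.stats import norm
        p = float(2 * norm.sf(abs(qbar) / se))
    return PooledEstimate(qbar, w, b, t_var, df, se, p, m)
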