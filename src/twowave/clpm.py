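"""Two-wave cross-lagged panel models (CLPM).

Each model relates the child symptom composite (S) and one predictor
(P) measured at two waves.  Six focal parameters are estimated, using
the conventional labelling of the two-wave panel diagram:

======  =================================================
``a``   S1 -> S2 autoregression (symptom stability)
``b``   P1 -> P2 autoregression (predictor stability)
``c``   wave-1 covariance of S1 and P1 (covariate-residualized)
``d``   wave-2 residual covariance
``e``   P1 -> S2 cross-lag (predictor drives symptoms)
``f``   S1 -> P2 cross-lag (symptoms drive the predictor)
======  =================================================

The four demographic covariates (age, gender, time since displacement,
war exposure) are exogenous with paths to all four focal variables.
All focal variables and continuous covariates are z-standardized over
the analysis sample before fitting, so coefficients are standardized
betas; binary gender stays 0/1-coded.

Estimation is equation-wise least squares: S2 on (S1, P1, covariates)
and P2 on (P1, S1, covariates).  The model is just identified
(saturated), so these estimates coincide with full maximum-likelihood
path analysis and the model-implied covariance matrix of the focal
variables reproduces the sample covariance exactly — that saturation
identity is the fit check, since no fit indices exist for a saturated
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import COVARIATE_NAMES
from .impute import ImputedDatasets, rubin_pool

__all__ = ["CrossLaggedPanelModel", "CLPMResults", "fit_clpm",
           "fit_clpm_pooled"]

PATHS = ("a", "b", "c", "d", "e", "f")


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def _fisher_se_p(r: float, n: int, k_partial: int = 0):
    """Normal-theory SE and p for a correlation via the Fisher z
    transform, with ``k_partial`` variables partialled out."""
    dof = n - 3 - k_partial
    se_z = 1.0 / np.sqrt(dof)
    z = np.arctanh(np.clip(r, -0.999999, 0.999999))
    p = 2 * stats.norm.sf(abs(z) / se_z)
    se_r = (1 - r * r) * se_z  # delta method back-transform
    return float(se_r), float(p)


@dataclass
class CLPMResults:
    """Estimates from one fitted (possibly pooled) panel model."""

    predictor: str
    params: pd.Series              # indexed by the path labels a..f
    bse: pd.Series
    pvalues: pd.Series
    nobs: int
    standardized: bool
    covariate_effects: pd.DataFrame    # (covariate x focal-equation) betas
    sample_cov: np.ndarray             # 4x4 over (S1, P1, S2, P2), residualized
    resid_cov: np.ndarray              # 2x2 wave-2 residual covariance
    pooled: bool = False
    m: int | None = None
    var_order: tuple[str, ...] = ("S1", "P1", "S2", "P2")

    def implied_covariance(self) -> np.ndarray:
        """Model-implied covariance of (S1, P1, S2, P2) by path tracing.

        With B = [[a, e], [f, b]] mapping wave 1 onto wave 2,
        the implied blocks are V1 (free), V1 B', and B V1 B' + Psi.
        For a just-identified model this reproduces the sample
        covariance to numerical tolerance.
        """
        a, b, e, f = (self.params[k] for k in ("a", "b", "e", "f"))
        B = np.array([[a, e], [f, b]])
        V1 = self.sample_cov[:2, :2]
        V2 = B @ V1 @ B.T + self.resid_cov
        C12 = V1 @ B.T
        top = np.hstack([V1, C12])
        bottom = np.hstack([C12.T, V2])
        return np.vstack([top, bottom])

    def summary(self) -> str:
        stars = self.pvalues.map(
            lambda p: "***" if p < 0.001 else "**" if p < 0.01
            else "*" if p < 0.05 else "")
        head = f"Cross-lagged panel model: symptom composite x {self.predictor}"
        if self.pooled:
            head += f" (pooled over m={self.m} imputations)"
        lines = [head, f"  n = {self.nobs}, standardized = {self.standardized}",
                 "  path   beta      se       p"]
        for k in PATHS:
            lines.append(f"  {k:>4s}  {self.params[k]: .3f}  "
                         f"{self.bse[k]:.3f}  {self.pvalues[k]:.4f} {stars[k]}")
        return "\n".join(lines)

    def to_row(self) -> dict:
        row = {"predictor": self.predictor, "n": self.nobs}
        for k in PATHS:
            row[k] = self.params[k]
            row[f"se_{k}"] = self.bse[k]
            row[f"p_{k}"] = self.pvalues[k]
        return row


class CrossLaggedPanelModel:
    """Saturated two-wave panel model of one predictor and the symptom
    composite.

    ``data`` must contain ``symptom_w1``/``symptom_w2`` (see
    :func:`twowave.scoring.add_composite`), ``<predictor>_w1``/``_w2``
    and the covariates.  Rows with missing values on any analysis
    variable are not allowed — impute first and use
    :meth:`fit_pooled` (or :func:`fit_clpm_pooled`).
    """

    def __init__(self, data: pd.DataFrame, predictor: str,
                 symptom: str = "symptom",
                 covariates: Sequence[str] = COVARIATE_NAMES,
                 standardize: bool = True):
        self.predictor = predictor
        self.symptom = symptom
        self.covariates = tuple(covariates)
        self.standardize = standardize
        cols = [f"{symptom}_w1", f"{symptom}_w2",
                f"{predictor}_w1", f"{predictor}_w2", *self.covariates]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise KeyError(f"missing analysis columns: {missing}")
        if data[cols].isna().any().any():
            raise ValueError(
                "incomplete analysis variables; impute first and fit the "
                "pooled model")
        self.data = data
        self._cols = cols

    def _prepare(self):
        d = self.data
        n = len(d)
        n_params = 6 + 4 * len(self.covariates)
        if n <= n_params:
            raise ValueError(f"n={n} is not larger than the parameter "
                             f"count {n_params}")
        arrays = {}
        for c in self._cols:
            x = d[c].to_numpy(dtype=float)
            binary = len(np.unique(x)) <= 2
            if self.standardize and not binary:
                if x.std(ddof=1) == 0:
                    raise ValueError(f"rank-deficient design: {c!r} constant")
                x = _zscore(x)
            arrays[c] = x
        return arrays, n

    def fit(self) -> CLPMResults:
        arrays, n = self._prepare()
        s1 = arrays[f"{self.symptom}_w1"]
        s2 = arrays[f"{self.symptom}_w2"]
        p1 = arrays[f"{self.predictor}_w1"]
        p2 = arrays[f"{self.predictor}_w2"]
        Z = np.column_stack([arrays[c] for c in self.covariates]) \
            if self.covariates else np.empty((n, 0))

        ones = np.ones(n)
        X2 = np.column_stack([ones, s1, p1, Z])
        if np.linalg.matrix_rank(X2) < X2.shape[1]:
            raise ValueError("rank-deficient design matrix")
        fit_s = sm.OLS(s2, X2).fit()
        fit_p = sm.OLS(p2, np.column_stack([ones, p1, s1, Z])).fit()

        # wave-1 association: correlation of covariate-residualized scores
        XZ = np.column_stack([ones, Z])
        rs1 = sm.OLS(s1, XZ).fit().resid
        rp1 = sm.OLS(p1, XZ).fit().resid
        rs2 = sm.OLS(s2, XZ).fit().resid
        rp2 = sm.OLS(p2, XZ).fit().resid
        kz = Z.shape[1]
        c_cov = float(np.cov(rs1, rp1, ddof=1)[0, 1])
        c_corr = c_cov / (rs1.std(ddof=1) * rp1.std(ddof=1))
        se_c, p_c = _fisher_se_p(c_corr, n, kz)

        # wave-2 residual covariance from the two fitted equations
        es, ep = fit_s.resid, fit_p.resid
        resid_cov = np.cov(np.vstack([es, ep]), ddof=1)
        d_corr = resid_cov[0, 1] / np.sqrt(resid_cov[0, 0] * resid_cov[1, 1])
        se_d, p_d = _fisher_se_p(d_corr, n, kz + 2)

        params = pd.Series({
            "a": fit_s.params[1], "e": fit_s.params[2],
            "b": fit_p.params[1], "f": fit_p.params[2],
            "c": c_corr, "d": d_corr,
        }).reindex(PATHS)
        bse = pd.Series({
            "a": fit_s.bse[1], "e": fit_s.bse[2],
            "b": fit_p.bse[1], "f": fit_p.bse[2],
            "c": se_c, "d": se_d,
        }).reindex(PATHS)
        pvalues = pd.Series({
            "a": fit_s.pvalues[1], "e": fit_s.pvalues[2],
            "b": fit_p.pvalues[1], "f": fit_p.pvalues[2],
            "c": p_c, "d": p_d,
        }).reindex(PATHS)

        cov_eff = pd.DataFrame(
            {f"{self.symptom}_w2": fit_s.params[3:3 + kz],
             f"{self.predictor}_w2": fit_p.params[3:3 + kz]},
            index=list(self.covariates))

        sample_cov = np.cov(np.vstack([rs1, rp1, rs2, rp2]), ddof=1)
        return CLPMResults(
            predictor=self.predictor, params=params, bse=bse,
            pvalues=pvalues, nobs=n, standardized=self.standardize,
            covariate_effects=cov_eff, sample_cov=sample_cov,
            resid_cov=resid_cov,
        )

    def fit_pooled(self, imputed: ImputedDatasets) -> CLPMResults:
        """Per-copy fits combined path-wise by Rubin's rules.

        P-values use large-sample normal theory on the pooled
        estimates.
        """
        fits = [CrossLaggedPanelModel(d, self.predictor, self.symptom,
                                      self.covariates, self.standardize).fit()
                for d in imputed]
        params, bse, pvalues = {}, {}, {}
        for k in PATHS:
            pooled = rubin_pool([f.params[k] for f in fits],
                                [f.bse[k] ** 2 for f in fits])
            params[k] = pooled.estimate
            bse[k] = pooled.se
            pvalues[k] = float(2 * stats.norm.sf(
                abs(pooled.estimate) / pooled.se)) if pooled.se > 0 else \
                (1.0 if pooled.estimate == 0 else 0.0)
        first = fits[0]
        return CLPMResults(
            predictor=self.predictor,
            params=pd.Series(params).reindex(PATHS),
            bse=pd.Series(bse).reindex(PATHS),
            pvalues=pd.Series(pvalues).reindex(PATHS),
            nobs=first.nobs, standardized=self.standardize,
            covariate_effects=sum(f.covariate_effects for f in fits) / len(fits),
            sample_cov=np.mean([f.sample_cov for f in fits], axis=0),
            resid_cov=np.mean([f.resid_cov for f in fits], axis=0),
            pooled=True, m=len(fits),
        )


def fit_clpm(data: pd.DataFrame, predictor: str,
             covariates: Sequence[str] = COVARIATE_NAMES,
             symptom: str = "symptom", standardize: bool = True,
             ) -> CLPMResults:
    """Convenience wrapper: build and fit one panel model."""
    return CrossLaggedPanelModel(data, predictor, symptom, covariates,
                                 standardize).fit()


def fit_clpm_pooled(imputed: ImputedDatasets, predictor: str,
                    covariates: Sequence[str] = COVARIATE_NAMES,
                    symptom: str = "symptom", standardize: bool = True,
                    ) -> CLPMResults:
    """Fit on every imputed copy and pool path-wise."""
    model = CrossLaggedPanelModel(imputed.datasets[0], predictor, symptom,
                                  covariates, standardize)
    return model.fit_pooled(imputed)
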