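"""Synthetic two-wave dyad cohorts with known ground truth.

Two kinds of datasets come out of this module:

* :func:`generate_cohort` draws stochastic cohorts whose focal predictor
  and symptom composite follow the standardized cross-lagged structure
  in :class:`~twowave.config.EffectSpec` exactly on the latent scale,
  then maps latents onto bounded integer symptom scales and bounded
  continuous predictors.  These support parameter-recovery and
  calibration experiments.
* :func:`generate_fixture_transitions` builds a deterministic cohort in
  which the trajectory classifier reproduces a requested set of group
  counts exactly, bypassing the stochastic path entirely.  Fixtures
  realise worked examples such as the printed 553/238/101/90 transition
  table.

:func:`amputate` punches missing-at-random (or completely-at-random)
holes into predictor columns only — symptom scales and covariates are
never amputated, mirroring a design in which demographics, war exposure
and child mental health are fully observed.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .config import (
    COVARIATE_NAMES,
    CohortConfig,
    ConfigurationError,
    ScaleSpec,
    default_scale_specs,
)

__all__ = ["generate_cohort", "amputate", "generate_fixture_transitions",
           "predictor_columns"]


def _truncated_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _draw_covariates(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    cs = config.covariate_spec
    n = config.n_dyads
    age = _truncated_normal(rng, cs.age_mean, cs.age_sd, *cs.age_range, n)
    gender = (rng.random(n) < cs.female_rate).astype(int)  # 1 = girl
    time = _truncated_normal(rng, cs.time_mean, cs.time_sd, *cs.time_range, n)
    war = np.clip(
        np.rint(rng.normal(cs.war_mean, cs.war_sd, n)),
        cs.war_range[0], cs.war_range[1],
    ).astype(int)
    return pd.DataFrame({
        "age": np.round(age, 2),
        "gender": gender,
        "time_since_leaving": np.round(time, 2),
        "war_events": war,
    })


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def _draw_focal_latents(config: CohortConfig, covariates: pd.DataFrame,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Standardized (symptom, predictor) pair at both waves.

    The w2 residual scale is set from the sample variance of the
    systematic part so that every focal variable has unit variance in
    the realised cohort; a systematic variance at or above one means the
    requested effect sizes are incompatible and raises a configuration
    error naming the offending paths.
    """
    spec = config.effect_spec
    spec.validate()
    n = config.n_dyads
    Z = np.column_stack([_standardize(covariates[c].to_numpy(dtype=float))
                         for c in COVARIATE_NAMES])

    def loading_vec(var: str) -> np.ndarray:
        row = spec.covariate_loadings[var]
        return np.array([row[c] for c in COVARIATE_NAMES])

    def residual_pair(sys1, sys2, corr, labels):
        v1 = 1.0 - np.var(sys1, ddof=1)
        v2 = 1.0 - np.var(sys2, ddof=1)
        for v, lab in ((v1, labels[0]), (v2, labels[1])):
            if v <= 0:
                raise ConfigurationError(
                    f"implied covariance is not positive definite: systematic "
                    f"variance of {lab} reaches {1 - v:.3f} >= 1"
                )
        cov = np.array([[v1, corr * np.sqrt(v1 * v2)],
                        [corr * np.sqrt(v1 * v2), v2]])
        return rng.multivariate_normal([0.0, 0.0], cov, size=n)

    sys_s1 = Z @ loading_vec("symptom_w1")
    sys_p1 = Z @ loading_vec("predictor_w1")
    res1 = residual_pair(sys_s1, sys_p1, spec.within_time_correlation_w1,
                         ("symptom_w1", "predictor_w1"))
    s1 = sys_s1 + res1[:, 0]
    p1 = sys_p1 + res1[:, 1]

    sys_s2 = (Z @ loading_vec("symptom_w2")
              + spec.stability_symptom * s1
              + spec.crosslag_pred_to_symptom * p1)
    sys_p2 = (Z @ loading_vec("predictor_w2")
              + spec.stability_predictor * p1
              + spec.crosslag_symptom_to_pred * s1)
    res2 = residual_pair(sys_s2, sys_p2, spec.residual_correlation_w2,
                         ("symptom_w2", "predictor_w2"))
    s2 = sys_s2 + res2[:, 0]
    p2 = sys_p2 + res2[:, 1]
    return pd.DataFrame({
        "symptom_w1": s1, "predictor_w1": p1,
        "symptom_w2": s2, "predictor_w2": p2,
    })


def _scale_totals(latent: np.ndarray, spec: ScaleSpec, wave: int,
                  noise: np.ndarray) -> np.ndarray:
    mean = spec.mean_w1 if wave == 1 else spec.mean_w2
    raw = mean + spec.sd * (latent + noise)
    return np.clip(np.rint(raw), 0, spec.maximum).astype(int)


def _map_predictor(latent, spec):
    raw = spec.mean + spec.sd * latent
    return np.round(np.clip(raw, *spec.bounds), 3)


def generate_cohort(config: CohortConfig | None = None, *,
                    return_latent: bool = False):
    """Draw one synthetic cohort.

    Parameters
    ----------
    config
        Cohort recipe; the default reproduces the study conditions
        (n=982, standardized cross-lagged structure with a=b=0.5,
        e=0.10, f=0).
    return_latent
        When true, also return the standardized latent focal variables
        before rounding/clipping — useful for moment checks.

    Returns
    -------
    DataFrame (and optionally the latent DataFrame) in the wide dialect:
    ``dyad_id``, unsuffixed covariates, ``<scale>_w1``/``_w2`` integer
    totals and ``<predictor>_w1``/``_w2`` bounded continuous scores.
    Identical seed and config give byte-identical output.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_dyads

    covariates = _draw_covariates(config, rng)
    latent = _draw_focal_latents(config, covariates, rng)

    data = {"dyad_id": np.arange(1, n + 1)}
    data.update({c: covariates[c] for c in COVARIATE_NAMES})

    for wave, sym in ((1, latent["symptom_w1"]), (2, latent["symptom_w2"])):
        for spec in config.scale_specs:
            noise = rng.normal(0.0, config.scale_noise_sd, n)
            data[f"{spec.name}_w{wave}"] = _scale_totals(
                sym.to_numpy(), spec, wave, noise)

    for pspec in config.predictor_specs:
        if pspec.name == config.focal_predictor:
            lat1, lat2 = latent["predictor_w1"], latent["predictor_w2"]
        else:
            rho = config.nuisance_stability
            z1 = rng.standard_normal(n)
            z2 = rho * z1 + np.sqrt(1 - rho * rho) * rng.standard_normal(n)
            lat1, lat2 = z1, z2
        data[f"{pspec.name}_w1"] = _map_predictor(np.asarray(lat1), pspec)
        data[f"{pspec.name}_w2"] = _map_predictor(np.asarray(lat2), pspec)

    df = pd.DataFrame(data)
    if config.missing_rate > 0:
        df = amputate(df, config.missing_rate, mechanism="MCAR",
                      seed=int(rng.integers(2**31)))
    if return_latent:
        return df, latent
    return df


def predictor_columns(df: pd.DataFrame,
                      scale_names: Iterable[str] = ("ptsd", "dep", "ext"),
                      ) -> list[str]:
    """Wave-suffixed predictor columns (everything that is not an id,
    covariate or symptom-scale column)."""
    reserved = {"dyad_id", *COVARIATE_NAMES}
    reserved |= {f"{s}_w{w}" for s in scale_names for w in (1, 2)}
    reserved |= {"symptom_w1", "symptom_w2"}
    return [c for c in df.columns
            if c not in reserved and (c.endswith("_w1") or c.endswith("_w2"))]


def amputate(df: pd.DataFrame, missing_rate: float, mechanism: str = "MCAR",
             seed: int = 0, condition_on: str | None = None,
             columns: Sequence[str] | None = None,
             mar_slope: float = 1.0) -> pd.DataFrame:
    """Introduce missingness into predictor columns.

    MCAR deletes each predictor cell independently with probability
    ``missing_rate``.  MAR makes the per-row deletion probability a
    logistic function of a fully observed conditioning variable
    (``condition_on``, e.g. the war-event count), with the intercept
    calibrated so the expected overall fraction still equals
    ``missing_rate``.  Symptom scales and covariates are never touched.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")
    out = df.copy()
    if missing_rate == 0.0:
        return out
    cols = list(columns) if columns is not None else predictor_columns(df)
    rng = np.random.default_rng(seed)
    n = len(df)

    if mechanism.upper() == "MCAR":
        prob = np.full(n, missing_rate)
    elif mechanism.upper() == "MAR":
        if condition_on is None:
            raise ValueError("MAR amputation requires condition_on")
        z = _standardize(df[condition_on].to_numpy(dtype=float))

        def excess(b0):
            return expit(b0 + mar_slope * z).mean() - missing_rate

        b0 = brentq(excess, logit(1e-6), logit(1 - 1e-6))
        prob = expit(b0 + mar_slope * z)
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")

    for col in cols:
        mask = rng.random(n) < prob
        out.loc[mask, col] = np.nan
    return out


# ---------------------------------------------------------------------------
# deterministic fixtures

# per-group (w1 totals, w2 totals) on (ptsd, dep, ext); chosen so the
# trajectory rules fire unambiguously: cut-offs 12/10/12 and a >=20%
# change on every scale whose status flips
_FIXTURE_TOTALS = {
    "SHR": ((20, 0, 0), (20, 0, 0)),            # above PTSD cut-off twice
    "improving": ((20, 0, 0), (8, 0, 0)),       # crossed down, -60%
    "deteriorating": ((8, 0, 0), (20, 0, 0)),   # crossed up, +150%
    "SLR": ((4, 2, 3), (5, 2, 3)),              # below all cut-offs twice
}

#: positional order for count sequences: (SHR, improving, deteriorating, SLR)
_GROUP_ORDER = ("SHR", "improving", "deteriorating", "SLR")


def generate_fixture_transitions(counts, config: CohortConfig | None = None,
                                 ) -> pd.DataFrame:
    """Deterministic cohort realising exact trajectory-group counts.

    ``counts`` maps group label to size, or is a (SHR, deteriorating,
    improving, SLR) sequence.  Scale totals are set directly so the
    classifier reproduces the requested counts for any non-negative
    input; predictors and covariates are filled with deterministic
    in-range values.
    """
    if not isinstance(counts, dict):
        counts = dict(zip(_GROUP_ORDER, counts))
    unknown = set(counts) - set(_GROUP_ORDER)
    if unknown:
        raise ValueError(f"unknown trajectory labels: {sorted(unknown)}")
    if any(v < 0 for v in counts.values()):
        raise ValueError("group counts must be non-negative")
    config = config or CohortConfig()

    rows = []
    i = 0
    for label in _GROUP_ORDER:
        w1, w2 = _FIXTURE_TOTALS[label]
        for _ in range(int(counts.get(label, 0))):
            row = {
                "dyad_id": i + 1,
                "age": 8 + (i % 9),
                "gender": i % 2,
                "time_since_leaving": float(i % 6),
                "war_events": i % 26,
                "ptsd_w1": w1[0], "dep_w1": w1[1], "ext_w1": w1[2],
                "ptsd_w2": w2[0], "dep_w2": w2[1], "ext_w2": w2[2],
            }
            for pspec in config.predictor_specs:
                lo, hi = pspec.bounds
                span = hi - lo
                row[f"{pspec.name}_w1"] = round(lo + span * ((i % 7) / 6.0), 3)
                row[f"{pspec.name}_w2"] = round(lo + span * ((i % 5) / 4.0), 3)
            rows.append(row)
            i += 1
    if not rows:  # empty cohort: preserve schema
        cols = ["dyad_id", *COVARIATE_NAMES]
        cols += [f"{s.name}_w{w}" for w in (1, 2) for s in default_scale_specs()]
        cols += [f"{p.name}_w{w}" for p in config.predictor_specs for w in (1, 2)]
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)
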