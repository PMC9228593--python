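"""Configuration objects for the synthetic two-wave cohort generator.

The generator simulates child--caregiver dyads measured twice, one year
apart: three bounded symptom scales (PTSD, depression, externalising
problems), a battery of continuous predictors at the individual, family
and community level, and four covariates (age, gender, time since
displacement, war-event count).  The focal predictor and the symptom
composite follow a standardized two-wave cross-lagged structure defined
by :class:`EffectSpec`; everything else is nuisance structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScaleSpec",
    "PredictorSpec",
    "CovariateSpec",
    "EffectSpec",
    "CohortConfig",
    "ConfigurationError",
    "default_scale_specs",
    "default_predictor_specs",
]

#: canonical symptom scale short names, in reporting order
SCALE_NAMES = ("ptsd", "dep", "ext")

#: clinical cut-offs on the adjusted scale totals (PTSD, depression,
#: externalising); a child scoring at or above any one is high risk
DEFAULT_CUTOFFS = (12, 10, 12)

#: items per scale; totals divided by these give per-item scores
DEFAULT_ITEM_COUNTS = (17, 10, 22)

#: per-item maxima (PTSD/depression 0-3, externalising 0-2)
DEFAULT_ITEM_MAXIMA = (3, 3, 2)

COVARIATE_NAMES = ("age", "gender", "time_since_leaving", "war_events")

FOCAL_VARS = ("symptom_w1", "predictor_w1", "symptom_w2", "predictor_w2")


class ConfigurationError(ValueError):
    """Raised when a cohort configuration is internally inconsistent."""


@dataclass(frozen=True)
class ScaleSpec:
    """One bounded symptom scale.

    ``mean_w1``/``mean_w2`` and ``sd`` place the integer totals on the
    raw scale; the latent symptom composite is mapped through them.
    """

    name: str
    n_items: int
    item_max: int
    mean_w1: float
    mean_w2: float
    sd: float

    @property
    def maximum(self) -> int:
        return self.n_items * self.item_max


@dataclass(frozen=True)
class PredictorSpec:
    """A continuous/ordinal predictor with its raw-scale placement."""

    name: str
    mean: float = 3.0
    sd: float = 0.8
    bounds: tuple[float, float] = (1.0, 5.0)


@dataclass(frozen=True)
class CovariateSpec:
    """Distributional targets for the four demographic covariates."""

    age_range: tuple[float, float] = (8.0, 16.0)
    age_mean: float = 11.22
    age_sd: float = 2.34
    female_rate: float = 0.529
    time_mean: float = 3.3
    time_sd: float = 1.8
    time_range: tuple[float, float] = (0.0, 9.0)
    war_mean: float = 9.57
    war_sd: float = 5.47
    war_range: tuple[int, int] = (0, 25)


def _zero_loadings() -> dict[str, float]:
    return {name: 0.0 for name in COVARIATE_NAMES}


@dataclass
class EffectSpec:
    """Standardized two-wave cross-lagged structure.

    Path labels follow the usual two-wave panel diagram:

    - ``stability_symptom`` (a): symptom w1 -> symptom w2 autoregression
    - ``stability_predictor`` (b): predictor w1 -> w2 autoregression
    - ``within_time_correlation_w1`` (c): w1 correlation of the
      covariate-residualized focal variables
    - ``residual_correlation_w2`` (d): correlation of the w2 residuals
    - ``crosslag_pred_to_symptom`` (e): predictor w1 -> symptom w2
    - ``crosslag_symptom_to_pred`` (f): symptom w1 -> predictor w2

    ``covariate_loadings`` maps each focal variable to standardized
    effects of the four covariates on it.
    """

    stability_symptom: float = 0.5
    stability_predictor: float = 0.5
    crosslag_pred_to_symptom: float = 0.10
    crosslag_symptom_to_pred: float = 0.0
    within_time_correlation_w1: float = 0.3
    residual_correlation_w2: float = 0.2
    covariate_loadings: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        defaults = {
            "symptom_w1": {"age": 0.05, "gender": -0.05,
                           "time_since_leaving": 0.0, "war_events": 0.25},
            "symptom_w2": {"age": 0.0, "gender": 0.0,
                           "time_since_leaving": 0.0, "war_events": 0.10},
            "predictor_w1": _zero_loadings(),
            "predictor_w2": _zero_loadings(),
        }
        merged = {}
        for var in FOCAL_VARS:
            row = dict(defaults[var])
            row.update(self.covariate_loadings.get(var, {}))
            unknown = set(row) - set(COVARIATE_NAMES)
            if unknown:
                raise ConfigurationError(
                    f"unknown covariates in loadings for {var}: {sorted(unknown)}"
                )
            merged[var] = row
        self.covariate_loadings = merged

    def validate(self) -> None:
        """Check that the implied standardized system is well defined.

        Raises :class:`ConfigurationError` naming the offending
        parameters when a correlation leaves (-1, 1) or the residual
        variance of a focal variable would be non-positive.
        """
        bad = []
        for label, value in [
            ("within_time_correlation_w1", self.within_time_correlation_w1),
            ("residual_correlation_w2", self.residual_correlation_w2),
        ]:
            if not -1.0 < value < 1.0:
                bad.append(f"{label}={value}")
        if bad:
            raise ConfigurationError(
                "correlations must lie strictly inside (-1, 1): " + ", ".join(bad)
            )
        for var in ("symptom_w1", "predictor_w1"):
            load = np.array(list(self.covariate_loadings[var].values()))
            if load @ load >= 1.0:
                raise ConfigurationError(
                    f"covariate loadings on {var} leave non-positive residual "
                    f"variance (sum of squares {load @ load:.3f} >= 1)"
                )
        a, b = self.stability_symptom, self.stability_predictor
        e, f = self.crosslag_pred_to_symptom, self.crosslag_symptom_to_pred
        c = self.within_time_correlation_w1
        # systematic variance of each w2 focal variable from its w1 parents
        var_s2 = a * a + e * e + 2 * a * e * c
        var_p2 = b * b + f * f + 2 * b * f * c
        for label, v, params in [
            ("symptom_w2", var_s2,
             "stability_symptom/crosslag_pred_to_symptom"),
            ("predictor_w2", var_p2,
             "stability_predictor/crosslag_symptom_to_pred"),
        ]:
            load = np.array(list(self.covariate_loadings[label].values()))
            if v + load @ load >= 1.0:
                raise ConfigurationError(
                    f"implied covariance is not positive definite: systematic "
                    f"variance of {label} is {v + load @ load:.3f} >= 1 "
                    f"(check {params} and covariate loadings)"
                )


def default_scale_specs() -> tuple[ScaleSpec, ...]:
    """Scale placements matching the cohort's printed prevalences.

    Means fall between waves so that the above-cut-off proportions drop
    from roughly 55/38/44% at baseline to 34/27/42% at follow-up.
    """
    return (
        ScaleSpec("ptsd", 17, 3, mean_w1=14.0, mean_w2=9.5, sd=9.0),
        ScaleSpec("dep", 10, 3, mean_w1=9.0, mean_w2=7.0, sd=6.0),
        ScaleSpec("ext", 22, 2, mean_w1=11.0, mean_w2=10.5, sd=7.0),
    )


_PREDICTOR_NAMES = (
    "optimism", "self_efficacy", "self_esteem", "environmental_sensitivity",
    "coping", "future_orientation", "child_health", "maternal_acceptance",
    "parental_monitoring", "parent_child_conflict", "maltreatment",
    "psychological_control", "caregiver_depression", "caregiver_anxiety",
    "caregiver_ptsd", "loneliness", "social_support", "bullying",
    "collective_efficacy", "refugee_environment",
)


def default_predictor_specs() -> tuple[PredictorSpec, ...]:
    """Twenty Likert-like predictors spanning child, family and community."""
    return tuple(PredictorSpec(name) for name in _PREDICTOR_NAMES)


@dataclass
class CohortConfig:
    """Full recipe for one synthetic cohort draw."""

    n_dyads: int = 982
    seed: int = 0
    scale_specs: tuple[ScaleSpec, ...] = field(default_factory=default_scale_specs)
    predictor_specs: tuple[PredictorSpec, ...] = field(
        default_factory=default_predictor_specs
    )
    effect_spec: EffectSpec = field(default_factory=EffectSpec)
    focal_predictor: str = "self_esteem"
    missing_rate: float = 0.0
    covariate_spec: CovariateSpec = field(default_factory=CovariateSpec)
    #: sd of per-scale deviations around the symptom latent; controls how
    #: tightly the three scales track the composite
    scale_noise_sd: float = 0.3
    #: first-order autoregression of the non-focal predictors
    nuisance_stability: float = 0.4

    def validate(self) -> None:
        if self.n_dyads <= 0:
            raise ConfigurationError("n_dyads must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        names = [p.name for p in self.predictor_specs]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate predictor names")
        if self.focal_predictor not in names:
            raise ConfigurationError(
                f"focal predictor {self.focal_predictor!r} not among predictors"
            )
        self.effect_spec.validate()

    @property
    def predictor_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.predictor_specs)
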