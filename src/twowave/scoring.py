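"""Scale scoring, per-wave risk status and trajectory classification.

A child is *high risk* at a wave if any of the three symptom totals
(PTSD, depression, externalising) reaches its clinical cut-off, and
*low risk* only if all three fall below.  Across the two waves each
child lands in exactly one of four trajectory groups:

========  =====================================================
SHR       high risk at both waves (stable high risk)
SLR       low risk at both waves (stable low risk / resilient)
improving high at w1, low at w2, with a drop of at least 20% on
          every scale that was above its cut-off at baseline
deteriorating  low at w1, high at w2, with a rise of at least
          20% on every scale newly above its cut-off
========  =====================================================

Children whose cut-off status flips without the accompanying 20%
change on the relevant scale(s) are classed by their baseline status
(SHR or SLR), so small reporting variability never counts as
categorical change.  A baseline total of zero on a newly crossing
scale is treated as meaningful change (relative change from zero is
undefined but crossing from zero is unambiguous worsening).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    DEFAULT_CUTOFFS,
    DEFAULT_ITEM_COUNTS,
    SCALE_NAMES,
    default_scale_specs,
)

__all__ = [
    "RiskStatus", "TrajectoryGroup", "TransitionSummary",
    "classify_risk", "composite_score", "assign_trajectory",
    "classify_cohort", "summarize_transitions", "add_composite",
]

LABELS = ("SHR", "deteriorating", "improving", "SLR")

_SCALE_MAXIMA = tuple(s.maximum for s in default_scale_specs())


class ScoreValidationError(ValueError):
    """A symptom total fell outside its scale's range."""


@dataclass(frozen=True)
class RiskStatus:
    wave: int
    above_cutoff: tuple[bool, bool, bool]
    overall: str  # "high" | "low"


@dataclass(frozen=True)
class TrajectoryGroup:
    label: str
    relevant_scales: tuple[str, ...]
    percent_changes: tuple[float, ...]


def _validate_totals(totals, record=None) -> tuple[float, ...]:
    totals = tuple(float(t) for t in totals)
    for name, total, maximum in zip(SCALE_NAMES, totals, _SCALE_MAXIMA):
        if not 0 <= total <= maximum:
            where = f" in record {record}" if record is not None else ""
            raise ScoreValidationError(
                f"{name} total {total}{where} outside [0, {maximum}]"
            )
    return totals


def classify_risk(totals, cutoffs=DEFAULT_CUTOFFS, wave: int = 1,
                  record=None) -> RiskStatus:
    """Per-wave risk status from the three scale totals.

    A total at or above its cut-off flags the scale; any flagged scale
    makes the child high risk for that wave.
    """
    totals = _validate_totals(totals, record)
    above = tuple(t >= c for t, c in zip(totals, cutoffs))
    return RiskStatus(wave, above, "high" if any(above) else "low")


def composite_score(totals, item_counts=DEFAULT_ITEM_COUNTS) -> float:
    """Mean of the per-item scale scores (each total / its item count).

    Used as the continuous symptom severity index in the panel models.
    """
    if any(k <= 0 for k in item_counts):
        raise ValueError("item counts must be positive")
    return float(np.mean([t / k for t, k in zip(totals, item_counts)]))


def _percent_change(w1: float, w2: float) -> float:
    """Signed relative change (w2-w1)/w1; +inf convention at w1=0."""
    if w1 == 0:
        return float("inf") if w2 > 0 else 0.0
    return (w2 - w1) / w1


def assign_trajectory(w1_totals, w2_totals, cutoffs=DEFAULT_CUTOFFS,
                      change_threshold: float = 0.20,
                      require_all_relevant: bool = True,
                      record=None) -> TrajectoryGroup:
    """Four-group trajectory label for one child.

    ``require_all_relevant`` demands the ≥ ``change_threshold`` relative
    change on *every* scale whose cut-off status flipped in the
    transition's direction; set it false to require it on any one.
    """
    w1_totals = _validate_totals(w1_totals, record)
    w2_totals = _validate_totals(w2_totals, record)
    above1 = [t >= c for t, c in zip(w1_totals, cutoffs)]
    above2 = [t >= c for t, c in zip(w2_totals, cutoffs)]
    high1, high2 = any(above1), any(above2)

    if high1 == high2:
        return TrajectoryGroup("SHR" if high1 else "SLR", (), ())

    if high1:  # candidate improving: every scale above at w1 must drop
        idx = [i for i, a in enumerate(above1) if a]
        changes = [_percent_change(w1_totals[i], w2_totals[i]) for i in idx]
        meaningful = [ch <= -change_threshold for ch in changes]
        ok = all(meaningful) if require_all_relevant else any(meaningful)
        label = "improving" if ok else "SHR"
    else:  # candidate deteriorating: every newly-above scale must rise
        idx = [i for i, a in enumerate(above2) if a]
        changes = [_percent_change(w1_totals[i], w2_totals[i]) for i in idx]
        meaningful = [ch >= change_threshold or ch == float("inf")
                      for ch in changes]
        ok = all(meaningful) if require_all_relevant else any(meaningful)
        label = "deteriorating" if ok else "SLR"
    return TrajectoryGroup(
        label,
        tuple(SCALE_NAMES[i] for i in idx),
        tuple(changes),
    )


def classify_cohort(df: pd.DataFrame, cutoffs=DEFAULT_CUTOFFS,
                    change_threshold: float = 0.20,
                    require_all_relevant: bool = True) -> pd.DataFrame:
    """Classify every dyad in a wide-format cohort.

    Returns a frame with the per-wave risk statuses, the trajectory
    label and the percent changes on the relevant scales.
    """
    required = [f"{s}_w{w}" for s in SCALE_NAMES for w in (1, 2)]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise KeyError(f"cohort is missing scale columns: {missing}")
    rows = []
    for rec in df.itertuples(index=False):
        rid = getattr(rec, "dyad_id", None)
        w1 = tuple(getattr(rec, f"{s}_w1") for s in SCALE_NAMES)
        w2 = tuple(getattr(rec, f"{s}_w2") for s in SCALE_NAMES)
        if any(pd.isna(v) for v in (*w1, *w2)):
            raise ScoreValidationError(
                f"record {rid}: symptom totals must be observed at both waves"
            )
        r1 = classify_risk(w1, cutoffs, wave=1, record=rid)
        r2 = classify_risk(w2, cutoffs, wave=2, record=rid)
        group = assign_trajectory(w1, w2, cutoffs, change_threshold,
                                  require_all_relevant, record=rid)
        rows.append({
            "dyad_id": rid,
            "risk_w1": r1.overall,
            "risk_w2": r2.overall,
            "trajectory": group.label,
            "relevant_scales": ";".join(group.relevant_scales),
            "percent_changes": ";".join(f"{c:.4g}" for c in group.percent_changes),
        })
    return pd.DataFrame(rows)


def add_composite(df: pd.DataFrame,
                  item_counts=DEFAULT_ITEM_COUNTS) -> pd.DataFrame:
    """Append ``symptom_w1``/``symptom_w2`` composite columns."""
    out = df.copy()
    for w in (1, 2):
        per_item = [df[f"{s}_w{w}"] / k for s, k in zip(SCALE_NAMES, item_counts)]
        out[f"symptom_w{w}"] = sum(per_item) / len(per_item)
    return out


@dataclass
class TransitionSummary:
    """Counts and percentages of the four trajectory groups."""

    counts: pd.Series                # indexed by label
    pct_total: pd.Series             # % of the full cohort
    pct_of_baseline_stratum: pd.Series  # % within baseline high/low
    n: int
    baseline_high_n: int
    baseline_low_n: int
    baseline_low_pct: float
    followup_low_pct: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "count": self.counts,
            "pct_total": self.pct_total,
            "pct_of_baseline_stratum": self.pct_of_baseline_stratum,
        })


def summarize_transitions(labels) -> TransitionSummary:
    """Transition table over trajectory labels.

    Percentages are reported both against the full cohort and within
    each baseline stratum (SHR/improving against baseline high risk,
    deteriorating/SLR against baseline low risk); each set sums to 100.
    """
    labels = pd.Series(list(labels), dtype="object")
    if labels.empty:
        raise ValueError("cannot summarise an empty cohort")
    counts = labels.value_counts().reindex(LABELS, fill_value=0)
    n = int(counts.sum())
    high_n = int(counts["SHR"] + counts["improving"])
    low_n = int(counts["deteriorating"] + counts["SLR"])
    denom = pd.Series(
        {"SHR": high_n, "improving": high_n,
         "deteriorating": low_n, "SLR": low_n}).reindex(LABELS)
    with np.errstate(invalid="ignore"):
        pct_strat = (counts / denom * 100).astype(float)
    followup_low = counts["improving"] + counts["SLR"]
    return TransitionSummary(
        counts=counts,
        pct_total=counts / n * 100,
        pct_of_baseline_stratum=pct_strat,
        n=n,
        baseline_high_n=high_n,
        baseline_low_n=low_n,
        baseline_low_pct=low_n / n * 100,
        followup_low_pct=followup_low / n * 100,
    )
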