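"""Reading and writing the wide-format cohort CSV dialect.

One row per child--caregiver dyad; per-wave variables carry ``_w1`` /
``_w2`` suffixes, covariates are unsuffixed, decimal separator is ".",
and an empty cell means missing (never zero).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .config import COVARIATE_NAMES, SCALE_NAMES

__all__ = ["read_cohort_csv", "write_cohort_csv", "SchemaError"]

REQUIRED_COLUMNS = tuple(COVARIATE_NAMES) + tuple(
    f"{s}_w{w}" for s in SCALE_NAMES for w in (1, 2))


class SchemaError(ValueError):
    """The cohort CSV does not match the expected wide schema."""


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a wide-format cohort CSV, validating the schema.

    Empty cells parse to NaN.  Symptom-scale totals and covariates must
    be fully observed; predictors may have gaps.
    """
    df = pd.read_csv(path, na_values=[""], keep_default_na=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort CSV {path} lacks required columns: {missing}")
    if "dyad_id" not in df.columns:
        df.insert(0, "dyad_id", range(1, len(df) + 1))
    problems = []
    for col in REQUIRED_COLUMNS:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna()].tolist()
        if bad:
            problems.append(f"{col} (rows {bad[:5]}{'...' if len(bad) > 5 else ''})")
        df[col] = numeric
    if problems:
        raise SchemaError(
            "missing or non-numeric values in fully observed columns: "
            + "; ".join(problems))
    return df


def write_cohort_csv(df: pd.DataFrame, path) -> str:
    """Write the wide dialect; missing cells become empty strings."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, na_rep="")
    return str(path)
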