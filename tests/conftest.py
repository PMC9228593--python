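import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")

from twowave.config import CohortConfig, EffectSpec
from twowave.scoring import add_composite
from twowave.simulate import generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort draw under the default study conditions (n=982)."""
    return add_composite(generate_cohort(CohortConfig(seed=42)))


@pytest.fixture(scope="session")
def null_crosslag_cohort():
    """Large cohort with both cross-lags switched off."""
    cfg = CohortConfig(
        n_dyads=10_000, seed=11,
        effect_spec=EffectSpec(crosslag_pred_to_symptom=0.0,
                               crosslag_symptom_to_pred=0.0),
    )
    return add_composite(generate_cohort(cfg))


def random_small_cohort(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Random symptom totals spanning the full scale ranges, biased
    toward the cut-off neighbourhoods so every branch of the
    trajectory rules gets exercised."""
    maxima = {"ptsd": 51, "dep": 30, "ext": 44}
    data = {"dyad_id": np.arange(1, n + 1)}
    for scale, mx in maxima.items():
        for w in (1, 2):
            near_cut = rng.integers(0, 25, size=n)
            wide = rng.integers(0, mx + 1, size=n)
            pick = rng.random(n) < 0.6
            data[f"{scale}_w{w}"] = np.where(pick, near_cut, wide).clip(0, mx)
    return pd.DataFrame(data)
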