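"""Shared fixtures: programmatically built cohorts and simulated worlds."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from icucausal.cohort import Cohort
from icucausal.simulate import scenario, simulate_cohort


def make_admissions_frame(
    n_clean: int = 20,
    n_weight_related: int = 0,
    n_repeat: int = 0,
    n_low_saps: int = 0,
    n_missing_saps: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Minimal admissions frame exercising every exclusion-cascade stage."""
    rng = np.random.default_rng(seed)
    total = n_clean + n_weight_related + n_repeat + n_low_saps + n_missing_saps
    df = pd.DataFrame({
        "admission_id": [f"A{i:06d}" for i in range(total)],
        "admission_seq": 1,
        "admission_reason_weight_related": pd.array([False] * total, dtype="boolean"),
        "saps2": rng.uniform(35.0, 90.0, total),
        "hospital_death": pd.array(rng.random(total) < 0.15, dtype="boolean"),
    })
    i = n_clean
    df.loc[i:i + n_weight_related - 1, "admission_reason_weight_related"] = True
    i += n_weight_related
    df.loc[i:i + n_repeat - 1, "admission_seq"] = 2
    i += n_repeat
    df.loc[i:i + n_low_saps - 1, "saps2"] = rng.uniform(5.0, 31.9, n_low_saps)
    i += n_low_saps
    df.loc[i:i + n_missing_saps - 1, "saps2"] = np.nan
    return df


@pytest.fixture(scope="session")
def complete_world():
    """A moderately sized fully observed synthetic cohort plus its truth."""
    cohort, truth = simulate_cohort(scenario("complete", n=6000, seed=123))
    return cohort, truth


@pytest.fixture(scope="session")
def default_world():
    """Default synthetic cohort (with MAR missingness) plus its truth."""
    cohort, truth = simulate_cohort(scenario("default", n=6557, seed=123))
    return cohort, truth


@pytest.fixture(scope="session")
def big_world():
    """Large fully observed cohort for calibration-style checks."""
    cohort, truth = simulate_cohort(scenario("default", n=1_000_000, seed=7))
    return cohort, truth
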