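"""Shared fixtures: synthetic reference tables and cohorts.

Reference studies publish per-stage mean/SD age statistics; only the male
stage means are public here, so all tables carrying SDs (and all female
values) are synthetic, chosen to be physiologically plausible for clavicle
maturation (stage means rising from the early teens to the early thirties,
within-stage SDs of one to a few years).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from clavage import (
    MALE_STAGE_MEANS,
    STAGE_LABELS,
    Cohort,
    ReferenceTable,
    StageReference,
)

# Synthetic per-stage age SDs (years), increasing toward the open-ended
# late stages as reference studies report.
SYNTH_SDS = {
    "1": 1.4,
    "2a": 1.1,
    "2b": 1.0,
    "2c": 0.9,
    "3a": 1.0,
    "3b": 1.2,
    "3c": 1.3,
    "4": 2.0,
    "5": 2.2,
}

# Synthetic female means: maturation runs ~1 year earlier than in males.
SYNTH_FEMALE_MEANS = {s: m - 1.0 for s, m in MALE_STAGE_MEANS.items()}


def make_table(
    means: dict[str, float], sds: dict[str, float], sex: str = "m"
) -> ReferenceTable:
    """Build a (possibly partial) one-sex table from stage → mean/SD maps."""
    entries = [
        StageReference(stage=s, sex=sex, mean_age=means[s], sd_age=sds[s])
        for s in means
    ]
    return ReferenceTable(entries, require_complete=False)


def two_stage_table(
    m1: float, m2: float, sd1: float, sd2: float, sex: str = "m"
) -> ReferenceTable:
    """Toy table with stages 2a and 3a only."""
    return make_table({"2a": m1, "3a": m2}, {"2a": sd1, "3a": sd2}, sex)


@pytest.fixture(scope="session")
def male_table() -> ReferenceTable:
    """Published male stage means with synthetic SDs."""
    return make_table(MALE_STAGE_MEANS, SYNTH_SDS, "m")


@pytest.fixture(scope="session")
def full_table() -> ReferenceTable:
    """Two-sex table: published male means, synthetic female means, synthetic SDs."""
    entries = [
        StageReference(s, "m", MALE_STAGE_MEANS[s], SYNTH_SDS[s])
        for s in STAGE_LABELS
    ] + [
        StageReference(s, "f", SYNTH_FEMALE_MEANS[s], SYNTH_SDS[s])
        for s in STAGE_LABELS
    ]
    return ReferenceTable(entries)


@pytest.fixture()
def small_cohort() -> Cohort:
    return Cohort(
        pd.DataFrame(
            {
                "id": ["a", "b", "c", "d"],
                "sex": ["f", "m", "f", "m"],
                "age": [16.5, 19.25, 22.0, 27.75],
            }
        )
    )


def random_complete_table(rng: np.random.Generator, sex: str = "m") -> ReferenceTable:
    """Random valid one-sex table with increasing means and positive SDs."""
    means = np.sort(rng.uniform(10.0, 35.0, size=len(STAGE_LABELS)))
    means += np.arange(len(means)) * 1e-3  # break exact ties
    sds = rng.uniform(0.3, 3.0, size=len(STAGE_LABELS))
    return make_table(
        dict(zip(STAGE_LABELS, means)), dict(zip(STAGE_LABELS, sds)), sex
    )
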