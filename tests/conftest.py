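import numpy as np
import pandas as pd
import pytest

from progdbn.cohort import Cohort
from progdbn.synthetic import (
    discretize_generated,
    generate_cohort,
    make_ground_truth,
)


@pytest.fixture(scope="session")
def small8_truth():
    return make_ground_truth("small8")


@pytest.fixture(scope="session")
def als_truth():
    return make_ground_truth("als_like")


@pytest.fixture(scope="session")
def small8_cohort(small8_truth):
    """A mid-sized raw cohort from the small preset (shared, read-only)."""
    return generate_cohort(small8_truth, 400, seed=11)


@pytest.fixture(scope="session")
def small8_discrete(small8_truth, small8_cohort):
    return discretize_generated(small8_truth, small8_cohort)


def make_toy_cohort(n_patients: int = 10, seed: int = 0) -> Cohort:
    """Tiny handmade cohort: two statics, two dynamic variables, some deaths."""
    rng = np.random.default_rng(seed)
    pids = [f"p{i}" for i in range(n_patients)]
    statics = pd.DataFrame(
        {
            "onset_delta": rng.uniform(100, 500, n_patients).round(),
            "age_onset": rng.uniform(40, 75, n_patients).round(1),
        },
        index=pd.Index(pids, name="patient_id"),
    )
    rows = []
    for i, pid in enumerate(pids):
        day = 0
        for _ in range(rng.integers(2, 5)):
            rows.append((pid, day, rng.uniform(30, 110), rng.uniform(45, 100)))
            day += int(rng.integers(20, 70))
    visits = pd.DataFrame(rows, columns=["patient_id", "day_offset", "fvc", "weight"])
    death = pd.Series(np.nan, index=statics.index)
    last = visits.groupby("patient_id")["day_offset"].max()
    for pid in pids[: n_patients // 3]:
        death[pid] = last[pid] + 30
    return Cohort(statics=statics, visits=visits, death_day=death)
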