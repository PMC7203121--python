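import numpy as np
import pytest

from apqscreen import cohort_from_pattern_table, published_pattern_table
from apqscreen.cohort import Cohort


@pytest.fixture(scope="session")
def published_table():
    return published_pattern_table()


@pytest.fixture(scope="session")
def reconstructed_cohort(published_table):
    """The 614-child cohort re-expanded from the published pattern table."""
    return cohort_from_pattern_table(published_table)


def make_random_cohort(rng: np.random.Generator, n_children: int, n_items: int,
                       missing_rate: float = 0.0) -> Cohort:
    """A small arbitrary cohort for oracle and property tests."""
    responses = (rng.random((n_children, n_items)) < rng.uniform(
        0.2, 0.8, size=n_items)).astype(float)
    if missing_rate:
        mask = rng.random((n_children, n_items)) < missing_rate
        responses[mask] = np.nan
    gold = rng.random(n_children) < rng.uniform(0.2, 0.8)
    if not gold.any():
        gold[0] = True
    if gold.all():
        gold[0] = False
    return Cohort(
        responses=responses,
        item_ids=tuple(f"q{j}" for j in range(n_items)),
        gold_label=gold,
        age_months=rng.integers(2, 60, size=n_children),
    )
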