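import numpy as np
import pandas as pd
import pytest

from chronodiet import recall_processing as rp
from chronodiet import synthetic_cohort as sc


@pytest.fixture(scope="session")
def small_cohort():
    """Default-spec cohort, n=400: (spec, participants, truth, recalls, outcomes)."""
    spec = sc.PopulationSpec(n_participants=400, seed=11)
    parts, truth, recalls, outcomes = sc.simulate_cohort(spec)
    return spec, parts, truth, recalls, outcomes


@pytest.fixture(scope="session")
def small_daily(small_cohort):
    """Retained daily exposure table with plausibility flags for small_cohort."""
    _, parts, _, recalls, _ = small_cohort
    daily = rp.flag_plausibility(rp.derive_daily_exposures_table(recalls), parts)
    retained, _ = rp.exclude_low_energy(daily)
    return retained


@pytest.fixture(scope="session")
def separated_cohort():
    """Well-separated archetypes with low noise: easy downstream recovery."""
    arch = sc.default_archetypes(separation=1.5)
    base = sc.PopulationSpec(n_participants=500, seed=23)
    ps = base.resolved_person_sd(arch) * 0.5
    spec = sc.PopulationSpec(
        n_participants=500,
        seed=23,
        person_sd=tuple(ps),
        within_ratio=0.3,
        recall_count_probs=(0.2, 0.3, 0.5),
    )
    parts, truth, recalls, outcomes = sc.simulate_cohort(spec, arch)
    return spec, arch, parts, truth, recalls, outcomes


def make_grouped_data(seed, n_groups=200, per_group=2, beta=(1.0, 0.5), sigma_u=0.7, sigma_e=1.0):
    """Simple random-intercept regression data for solver tests."""
    rng = np.random.default_rng(seed)
    n = n_groups * per_group
    g = np.repeat(np.arange(n_groups), per_group)
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = X @ np.asarray(beta) + rng.normal(0, sigma_u, n_groups)[g] + rng.normal(0, sigma_e, n)
    return y, X, g
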