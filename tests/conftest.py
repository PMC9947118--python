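"""Shared fixtures: small synthetic communities and fitted models.

Model fits are session-scoped because HMC is the expensive step; tests
treat them as read-only.
"""

from __future__ import annotations

import numpy as np
import pytest

from ichthyocarb import excretion
from ichthyocarb import mineralogy as mn
from ichthyocarb.synthetic import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def community():
    """Full-size synthetic community: 21 families, 175 observations."""
    ds, truth, raw = simulate_dataset(seed=11)
    return ds, truth, raw


@pytest.fixture(scope="session")
def small_community():
    """Small community for cheap fits: 8 families, 64 observations."""
    cfg = SimulationConfig(n_families=8, species_per_family=2, n_obs=64)
    ds, truth, raw = simulate_dataset(cfg, seed=29)
    return ds, truth, raw


@pytest.fixture(scope="session")
def excretion_fit(community):
    ds, truth, raw = community
    return excretion.fit(
        excretion.ExcretionModelSpec(),
        excretion.PriorSet(),
        ds,
        chains=2,
        iter=1000,
        warmup=500,
        seed=7,
    )


@pytest.fixture(scope="session")
def mineralogy_fit(community):
    ds, truth, raw = community
    return mn.fit_mineralogy(
        raw, chains=2, iter=800, warmup=450, seed=13
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
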