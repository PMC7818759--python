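"""Shared fixtures: small, seeded synthetic objects for fast tests."""

from __future__ import annotations

import numpy as np
import pytest

from traitnet.simulate import PlantedEffect, SimulationConfig, simulate_cohort_with_planted_effect


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def random_graph(rng: np.random.Generator, n: int, density: float = 0.5) -> np.ndarray:
    """Random symmetric non-negative adjacency with zero diagonal."""
    w = rng.uniform(0.05, 1.0, (n, n))
    mask = rng.random((n, n)) < density
    w = np.triu(w * mask, k=1)
    return w + w.T


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down cohort: full pipeline structure at a fraction of the cost."""
    return SimulationConfig(
        n_subjects=12,
        n_regions=30,
        n_timepoints=240,
        n_modules=3,
        voxels_per_region=(50, 200),
        samples_per_voxel=500,
        planted_effect=PlantedEffect(behaviour="SRS", metric="global_efficiency", rho=0.5),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort_with_planted_effect(small_config)
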