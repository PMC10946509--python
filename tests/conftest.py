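"""Shared fixtures: small synthetic worlds and species pools."""

import numpy as np
import pytest

from serloss.wilderness import classify_wilderness, exclude_empty_realms
from serloss.world import SERTruth, WorldConfig, generate_species_pool, generate_world


@pytest.fixture(scope="session")
def default_truth():
    return SERTruth.default(10)


@pytest.fixture(scope="session")
def small_world():
    """40x40 world with wilderness classified; realms kept as generated."""
    world = generate_world(WorldConfig(n_rows=40, n_cols=40, seed=7))
    mask = classify_wilderness(world.footprint, world.forest_potential,
                               world.intact_forest, world.productive,
                               realm=world.realm)
    world.wilderness = mask.wilderness
    kept, excluded = exclude_empty_realms(mask, world.realm)
    world.kept_realms = kept  # test convenience attributes
    world.wmask = mask
    return world


@pytest.fixture(scope="session")
def small_pool(small_world, default_truth):
    return generate_species_pool(small_world, default_truth, 300,
                                 extinct_prob=0.1, seed=11,
                                 range_median_cells=60)


@pytest.fixture(scope="session")
def default_world():
    """Default-size (100x100) world used by the heavier checks."""
    world = generate_world(WorldConfig(seed=42))
    mask = classify_wilderness(world.footprint, world.forest_potential,
                               world.intact_forest, world.productive,
                               realm=world.realm)
    world.wilderness = mask.wilderness
    kept, excluded = exclude_empty_realms(mask, world.realm)
    world.kept_realms = kept
    world.wmask = mask
    return world


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
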