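import numpy as np
import pytest

import lesionmap as lm


@pytest.fixture(scope="session")
def grid16():
    """Tiny 16^3 grid at 2 mm for fast voxel-level tests."""
    return lm.toy_grid(16, 2.0)


@pytest.fixture(scope="session")
def grid64():
    """The standard 64^3 toy grid at 2 mm."""
    return lm.toy_grid(64, 2.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_mask(grid, rng, p=0.3):
    return lm.BinaryVolume(grid, rng.random(grid.shape) < p)


@pytest.fixture(scope="session")
def small_cohort():
    """One cached 60-patient simulated cohort for cross-module tests."""
    cfg = lm.SimulationConfig(n_patients=60, seed=11)
    records, lesions, truth = lm.simulate_cohort(cfg)
    return cfg, records, lesions, truth
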