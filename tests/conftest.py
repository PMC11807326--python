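import numpy as np
import pytest

from gliohab.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """A reduced-size cohort (coarse voxels, fewer patients) for fast tests."""
    return CohortConfig(n_mutant=10, n_wildtype=14, voxel_size_mm=6.0, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
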