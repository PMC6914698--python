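import numpy as np
import pytest

from wmhfreq.synth import (CohortConfig, make_lesion_probability_field,
                           make_phantom_anatomy, simulate_cohort)


@pytest.fixture(scope="session")
def anatomy16():
    """Small deterministic phantom shared across tests."""
    return make_phantom_anatomy(shape=(16, 16, 16), voxel_size_mm=(2, 2, 2), seed=3)


@pytest.fixture(scope="session")
def field16(anatomy16):
    return make_lesion_probability_field(anatomy16, max_p=0.2)


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny but complete two-cohort simulation."""
    cfg = CohortConfig(n_old=6, n_young=4, shape=(16, 16, 16),
                       n_directions_old=8, n_directions_young=12, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
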