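import numpy as np
import pytest

from connlife.parcellation import make_parcellation
from connlife.synthcohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_parcellation():
    """A 30-node parcellation: four RSNs plus a handful of 'other' nodes."""
    return make_parcellation(
        {"auditory": 4, "language": 9, "visuospatial": 6, "primary_visual": 2},
        n_other=9,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic 40-subject cohort with the default planted effects."""
    cfg = CohortConfig(n_subjects=40, seed=11, grid_shape=(12, 12, 6))
    subjects, truth = generate_cohort(cfg)
    return cfg, subjects, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
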