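import numpy as np
import pytest

from boldvar.cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small but non-degenerate cohort shared across read-only tests."""
    spec = CohortSpec(n_per_group=5, grid_dims=(8, 8, 8), n_timepoints=60,
                      seed=11, effect_size=0.5)
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
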