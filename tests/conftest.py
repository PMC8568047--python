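import warnings

import numpy as np
import pytest

from habitrace import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small imaging3 cohort shared across tests (4 fish, 150 ROIs each)."""
    cfg = CohortConfig(n_fish=4, rois_per_fish=150)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(cfg, seed=1234)


@pytest.fixture
def rng():
    return np.random.default_rng(99)
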