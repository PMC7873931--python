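import logging

import numpy as np
import pytest

from fpdkit import synth

logging.getLogger("fpdkit").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_pair():
    """One lesioned, swollen foot pair with ground truth (shared, read-only)."""
    params = synth.FootGenParams(
        met_lesion_frac=0.30,
        digit_lesion_fracs={2: (0.6, 0.0, 0.0), 3: (0.0, 0.0, 0.0), 4: (0.02, 0.02, 0.0)},
        swelling_factors={2: 1.0, 3: 1.25, 4: 1.0},
        seed=7,
    )
    return synth.generate_foot_pair(params)


@pytest.fixture(scope="session")
def intact_pair():
    return synth.generate_foot_pair(synth.FootGenParams(seed=3))


@pytest.fixture(scope="session")
def small_cohort():
    """50-foot stratified cohort (10 per level), shared across tests."""
    return synth.generate_cohort(synth.CohortSpec(n_per_level=10, seed=11))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
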