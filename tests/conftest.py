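import numpy as np
import pandas as pd
import pytest

from methylaging.synthetic_data import (
    SyntheticCohortConfig,
    generate_cohort,
    generate_regions,
)

# A mid-sized cohort shared by read-only tests (module-scoped: generation is
# the expensive step; tests must not mutate the returned objects).
SMALL = dict(n_samples=80, n_probes=1500, n_prc2_regions=12, n_age_cpgs=100)


@pytest.fixture(scope="module")
def small_config():
    return SyntheticCohortConfig(seed=11, **SMALL)


@pytest.fixture(scope="module")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="module")
def small_regions(small_config):
    return generate_regions(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
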