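import warnings

import numpy as np
import pytest

from satmep import cohort as co


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared by pipeline tests: behavior,
    tidy MEP amplitude table, and ground truth for 8 agents."""
    cfg = co.CohortConfig(n_participants=8, master_seed=2024)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        behavior, meps, truth = co.generate_mep_table(cfg)
    return cfg, behavior, meps, truth
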