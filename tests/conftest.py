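import numpy as np
import pytest

from tapvoice.cohort import sample_cohort, simulate_feature_table


@pytest.fixture(scope="session")
def small_cohort():
    """3 PD + 3 controls with full truth, for signal-level tests."""
    return sample_cohort(3, 3, scenario="paper_like", seed=7)


@pytest.fixture(scope="session")
def feature_table():
    """One 20+20 cohort feature table drawn from the generating model."""
    profiles, truth = sample_cohort(20, 20, scenario="paper_like", seed=11)
    return simulate_feature_table(profiles, truth), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
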