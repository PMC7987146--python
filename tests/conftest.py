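import numpy as np
import pytest

from roanmap.synthetic_cohort import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-condition cohort shared across read-only tests."""
    cfg = SimConfig(seed=11, n_per_breed=20, n_markers=800)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def perfect_cohort():
    """Fully penetrant, unmasked cohort: phenotype == carrier status."""
    cfg = SimConfig(seed=13, n_per_breed=25, n_markers=600,
                    penetrance=1.0, phenotype_masking_prob=0.0)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2021)
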