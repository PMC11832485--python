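import logging

import numpy as np
import pytest

from pdfuse.simulate import SimConfig, simulate_cohort

logging.disable(logging.INFO)


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale planted-signal cohort shared across tests."""
    config = SimConfig(n_snp=400, n_mri=100, seed=11)
    cohort, truth = simulate_cohort(config)
    return cohort, truth, config


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no class signal in either modality."""
    config = SimConfig(
        n_snp=300, n_mri=80, snp_effect=0.0, mri_effect=0.0, seed=13
    )
    cohort, truth = simulate_cohort(config)
    return cohort, truth, config


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
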