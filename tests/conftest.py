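import numpy as np
import pytest

from presbyscan import audiogram_phenotype as ap
from presbyscan import cohort_sim as cs


@pytest.fixture(scope="session")
def basis():
    return ap.default_basis()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noiseless_cohort():
    cfg = cs.SimConfig(n_participants=120, n_variants=40, threshold_noise_sd=0.0,
                       seed=11)
    return cfg, cs.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def noisy_cohort():
    cfg = cs.SimConfig(n_participants=150, n_variants=60, threshold_noise_sd=3.0,
                       caller_disagreement_rate=0.05, seed=13,
                       maf_range=(0.01, 0.09))
    return cfg, cs.simulate_cohort(cfg)
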