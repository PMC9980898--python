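import numpy as np
import pytest

from connectomepred import synth


@pytest.fixture(scope="session")
def small_cohort():
    """60 subjects, 12 nodes, moderate planted effects; reused read-only."""
    truth = synth.make_truth(12, seed=0, n_sex_edges=8, sex_size=1.0,
                             n_age_edges=8, age_size=0.4,
                             scale_confound_beta=0.8)
    return synth.generate_cohort(60, 12, modalities=("SC", "FA"),
                                 truth=truth, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
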