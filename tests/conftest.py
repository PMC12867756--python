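import numpy as np
import pytest

from ilsrad import simnet


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def triplet_net():
    """((A,B),C)+O with the study-level internal branch."""
    return simnet.SpeciesNetwork.triplet(0.5184, outgroup_time=3.0)


@pytest.fixture(scope="session")
def study_net():
    return simnet.SpeciesNetwork.study_default()


@pytest.fixture(scope="session")
def small_genome(study_net):
    cfg = simnet.SimulationConfig(n_windows=25, window_len=600, theta=0.01,
                                  seed=11)
    return simnet.simulate_genome(cfg, study_net)
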