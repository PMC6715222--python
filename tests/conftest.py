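import numpy as np
import pytest

import smokesim as ss


@pytest.fixture(scope="session")
def default_marginals():
    return ss.default_marginals()


@pytest.fixture(scope="session")
def default_params():
    return ss.default_params()


@pytest.fixture
def simple_marginals():
    """Small, copula-free marginals for fast deterministic unit tests."""
    return ss.PopulationMarginals(
        stateProbs=np.array([0.80, 0.10, 0.05, 0.05]),
        friendCountProbs=np.array([0.5, 0.25, 0.15, 0.07, 0.03]),
        opennessCCDist={"kind": "survey_items", "itemProbs": [0.6, 0.2, 0.15, 0.05]},
        opennessECDist={"kind": "survey_items", "itemProbs": [0.6, 0.2, 0.15, 0.05]},
        freqUseDist={"kind": "discrete", "values": [0.1, 0.5, 1.0], "probs": [0.3, 0.3, 0.4]},
    )


@pytest.fixture
def small_population(simple_marginals):
    """60 agents with an assigned close-friend network."""
    profiles = ss.generate_profiles(60, simple_marginals, seed=5)
    network = ss.build_scale_free(60, 2, seed=5)
    network = ss.assign_close_friends(network, profiles, seed=5)
    states = {p.agentId: p.state for p in profiles}
    return profiles, network, states
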