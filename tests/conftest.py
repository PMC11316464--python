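import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import foramenflow as ff

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study_config():
    return ff.SimulationConfig()


@pytest.fixture(scope="session")
def study_tree(study_config):
    """One 88-tip study-design tree (69 extant + 19 fossil), kernel cache warm."""
    tree, meta = ff.simulate_tree(study_config, 11)
    tree.shared_times()
    return tree, meta["fossil_tips"]


@pytest.fixture(scope="session")
def study_table(study_config, study_tree):
    tree, fossil = study_tree
    return ff.simulate_allometry(tree, study_config, 12, fossil_tips=fossil)


@pytest.fixture
def four_tip_tree():
    return ff.read_tree("((A:1,B:1.5):1,(C:0.8,D:2):0.5);")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
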