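import numpy as np
import pytest

from sirkit.cohort import simulate_participant
from sirkit.config import CohortConfig, StimulusConfig
from sirkit.stimuli import make_base_faces


@pytest.fixture(scope="session")
def stim_cfg():
    return StimulusConfig()


@pytest.fixture(scope="session")
def base_faces(stim_cfg):
    """One base identity set shared by the stimulus tests."""
    return make_base_faces(stim_cfg, np.random.default_rng(1234))


@pytest.fixture(scope="session")
def demo_cfg():
    return CohortConfig.demo(seed=1)


@pytest.fixture(scope="session")
def young_participant(demo_cfg):
    """A single demo-scale young participant, reused across modules."""
    return simulate_participant(demo_cfg, "young", 42)
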