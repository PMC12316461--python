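import numpy as np
import pytest

from sociodyn.markov import BehaviorSequence
from sociodyn.simulate import default_scenario, gen_pose_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def alternating_sequence():
    """ABABABA: the fully hand-checkable two-state alternating sequence."""
    return BehaviorSequence(list("ABABABA"))


@pytest.fixture
def noiseless_session():
    """Short noiseless pose session with three planted bouts."""
    bouts = [("social", 10.0, 14.0), ("object", 30.0, 32.5), ("social", 50.0, 53.0)]
    scn = default_scenario(duration=60.0, planted_bouts=bouts, keypoint_noise_sd=0.0, seed=7)
    track, truth = gen_pose_session(scn)
    return scn, track, truth
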