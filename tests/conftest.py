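import numpy as np
import pytest

from remaperiodic.simulate import SyntheticSpec, synth_rem_episode


@pytest.fixture(scope="session")
def short_episode():
    """One 300-s synthetic REM episode shared across detector/segmentation tests."""
    spec = SyntheticSpec(duration=300.0, seed=21)
    rec, gt = synth_rem_episode(spec)
    return spec, rec, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
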