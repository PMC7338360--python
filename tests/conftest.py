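import numpy as np
import pytest

from roawake import synth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_session():
    """One compact synthetic session shared by read-only tests."""
    cfg = synth.SimulationConfig(
        image_shape=(48, 48),
        state_schedule=[("quiet", 30.0), ("NREM", 40.0)],
        seed=99, vessel_mask_fraction=0.05)
    return synth.generate_session(cfg)
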