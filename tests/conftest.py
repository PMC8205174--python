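import numpy as np
import pytest

from larvascreen import FrameStack, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_stack(rng):
    """A 30-frame random 8-bit stack, 32x48 px."""
    return FrameStack(rng.integers(0, 256, size=(30, 32, 48)).astype(np.uint8))


@pytest.fixture
def tiny_config():
    """A 2x3-well quarter-resolution plate for fast simulation."""
    return SimulationConfig.reduced(rows=2, cols=3, seed=7)


@pytest.fixture
def tiny_plate(tiny_config):
    return tiny_config.plate_map()


def make_stack(frames, **kwargs):
    return FrameStack(np.asarray(frames), **kwargs)
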