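import numpy as np
import pytest
from scipy.spatial.transform import Rotation


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_rotation(seed: int) -> np.ndarray:
    return Rotation.random(random_state=np.random.RandomState(seed)).as_matrix()


def rotated(config, seed: int):
    """A rotated + translated copy of a BeadConfiguration."""
    out = config.copy()
    R = random_rotation(seed)
    shift = np.random.default_rng(seed).uniform(-5, 5, 3)
    out.positions = config.positions @ R.T + shift
    return out
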