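import numpy as np
import pytest

from msemap.design import generate_synthetic_design
from msemap.simulate import TruthField

VOXEL = np.array([1.5625, 1.5625, 1.0])


@pytest.fixture(scope="session")
def small_design():
    """A 6x5x4 jittered grid design (120 fiducials, 3 landmarks)."""
    return generate_synthetic_design((6, 5, 4), (35.0, 35.0, 35.0),
                                     jitter_sd=1.0, seed=1)


@pytest.fixture(scope="session")
def small_truth(small_design):
    """Smooth random truth field (max 3 mm) over the small design's region."""
    pos = small_design.positions
    box = np.stack([pos.min(axis=0) - 40.0, pos.max(axis=0) + 40.0])
    return TruthField.random(box, orders=(3, 3, 3), max_magnitude=3.0, seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
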