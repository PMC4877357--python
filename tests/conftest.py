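import numpy as np
import pytest

from crypticdiv import SynthSpec, gen_landmarks
from crypticdiv.morpho_geometry import LandmarkDataset


@pytest.fixture
def square_dataset():
    """Three specimens around a unit square, no symmetry, no sliders."""
    base = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    rng = np.random.default_rng(42)
    coords = np.stack([base + 0.02 * rng.standard_normal((4, 2))
                       for _ in range(3)])
    return LandmarkDataset(
        specimen_ids=["s1", "s2", "s3"], coords=coords,
        point_roles=["landmark"] * 4)


@pytest.fixture
def symmetric_dataset():
    """Object-symmetric template: 2 midline + 2 bilateral pairs."""
    base = np.array([
        [0.0, 1.0],    # midline top
        [0.0, -1.0],   # midline bottom
        [-1.0, 0.5],   # left 1
        [1.0, 0.5],    # right 1
        [-0.8, -0.5],  # left 2
        [0.8, -0.5],   # right 2
    ])
    rng = np.random.default_rng(7)
    coords = np.stack([base + 0.01 * rng.standard_normal((6, 2))
                       for _ in range(4)])
    return LandmarkDataset(
        specimen_ids=[f"s{i}" for i in range(4)], coords=coords,
        point_roles=["landmark"] * 6,
        pairing=[(2, 3), (4, 5)], midline=[0, 1])


@pytest.fixture
def null_landmarks():
    """Two groups with no mean shift (null for the mean-shape test)."""
    spec = SynthSpec(seed=11, n_per_group=(20, 20), shift_magnitude=0.0)
    return gen_landmarks(spec)
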