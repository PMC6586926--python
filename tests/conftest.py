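import numpy as np
import pytest

from osteotherm import DesignSpec, generate_dataset

SEED = 20251001


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture(scope="session")
def learning_set():
    """Default synthetic learning-set analogue (fixed seed)."""
    return generate_dataset(DesignSpec(seed=7, role="learning"))


@pytest.fixture(scope="session")
def test_set():
    """Smaller synthetic test-set analogue (fixed seed)."""
    return generate_dataset(DesignSpec(seed=11, role="test", n_per_subgroup=5))


def make_disk_mask(radius: int, pad: int = 10) -> np.ndarray:
    """Digital disk x^2 + y^2 <= r^2 on a padded canvas."""
    size = 2 * (radius + pad) + 1
    c = radius + pad
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2
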