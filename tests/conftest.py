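import numpy as np
import pytest

from trifibril import FibrilBlueprint, build_ideal_fibril


@pytest.fixture(scope="session")
def blueprint():
    return FibrilBlueprint()


@pytest.fixture(scope="session")
def fibril(blueprint):
    """Ideal six-layer full-length fibril used across the suites."""
    return build_ideal_fibril(blueprint)


@pytest.fixture(scope="session")
def small_fibril():
    """Two-layer fibril for cheap per-layer tests."""
    return build_ideal_fibril(FibrilBlueprint(n_layers=2))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_rotation(rng):
    """Uniform random rotation matrix (for rigid-motion invariance checks)."""
    from scipy.spatial.transform import Rotation
    return Rotation.random(random_state=np.random.RandomState(
        rng.integers(0, 2**31))).as_matrix()
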