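import numpy as np
import pytest

import boldsim as bs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def spec2d():
    return bs.VoxelSpec(2, 0.1)


@pytest.fixture(scope="session")
def spec3d():
    return bs.VoxelSpec(3, 0.1)


@pytest.fixture(scope="session")
def small_gm():
    """A small grey-matter-like continuous 2D voxel (few cylinders) for
    fast end-to-end runs."""
    return bs.make_fixture("gm_cylinders_2d", seed=11, width=0.04,
                           n_spins=500, te=0.01, dt=2e-4)
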