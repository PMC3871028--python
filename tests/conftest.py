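import logging

import numpy as np
import pytest

from lapcell.io import BinaryVolume
from lapcell.synth import SyntheticCellSpec, _ellipsoid, make_cell_mask

logging.getLogger("lapcell").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def ball_mask() -> BinaryVolume:
    """Voxelized solid ball, genus zero."""
    return BinaryVolume(_ellipsoid((21, 21, 21), (10, 10, 10), (8, 8, 8)))


@pytest.fixture(scope="session")
def torus_mask() -> BinaryVolume:
    """Voxelized solid torus, genus one."""
    g = np.ogrid[0:41, 0:41, 0:21]
    d = (np.sqrt((g[0] - 20.0) ** 2 + (g[1] - 20.0) ** 2) - 12.0) ** 2 + (g[2] - 10.0) ** 2
    return BinaryVolume(d <= 16.0)


@pytest.fixture(scope="session")
def handle_cell() -> BinaryVolume:
    """Synthetic cell mask with two handles (χ = −1)."""
    return make_cell_mask(SyntheticCellSpec(n_handles=2, rng_seed=7))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
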