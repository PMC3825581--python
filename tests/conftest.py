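import numpy as np
import pytest

import coactiv as ca


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_grid():
    """12^3 box of 4-mm voxels with an ellipsoidal mask, centred on 0 mm."""
    return ca.ellipsoid_grid((12, 12, 12), 4.0)


@pytest.fixture
def identity_grid():
    """Unit-voxel grid whose affine is the identity (voxel index == mm)."""
    shape = (9, 9, 9)
    return ca.BrainGrid(shape, np.eye(4), np.ones(shape, bool))


def random_db(grid, n_exp, rng, foci_range=(4, 13), subjects_range=(10, 31)):
    """Fully random (structureless) database of in-mask foci."""
    idx = grid.mask_indices
    exps = []
    for i in range(n_exp):
        nf = int(rng.integers(*foci_range))
        mm = grid.voxel_to_mm(idx[rng.integers(0, idx.shape[0], nf)].astype(float))
        exps.append(ca.Experiment(f"e{i}", int(rng.integers(*subjects_range)),
                                  np.atleast_2d(mm)))
    return ca.FociDatabase(exps)


@pytest.fixture
def random_db_factory():
    return random_db
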