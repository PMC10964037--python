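"""Shared fixtures: small grids, masks and synthetic sessions."""

import numpy as np
import pytest

from benfc.types import Bold4D, BrainMask, VolumeGrid


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def grid():
    return VolumeGrid.isotropic((6, 7, 6), 3.0)


@pytest.fixture()
def mask(grid):
    return BrainMask(grid, np.ones(grid.dims, bool))


@pytest.fixture()
def bold(grid, rng):
    data = rng.standard_normal((*grid.dims, 40))
    return Bold4D(grid, data, tr_s=2.4, subject_id="sub-001", session="pre")
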