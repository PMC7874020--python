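"""Shared fixtures: all test data is generated in-process."""

import numpy as np
import pytest

from epinet.images import Bold4D, VoxelMask
from epinet.synthetic import default_scan_spec, generate_scan, table1_fixture


@pytest.fixture(scope="session")
def recovery_spec():
    """The standard recovery conditions: anti-loading -0.7, T = 300,
    200 anticorrelated voxels."""
    return default_scan_spec(n_timepoints=300, rng_seed=7)


@pytest.fixture(scope="session")
def recovery_scan(recovery_spec):
    return generate_scan(recovery_spec)


@pytest.fixture(scope="session")
def whole_brain(recovery_spec):
    return VoxelMask(
        np.ones(recovery_spec.grid_shape, dtype=bool), recovery_spec.affine, "brain"
    )


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_bold(values, affine=None, tr_s=3.0) -> Bold4D:
    values = np.asarray(values, dtype=float)
    if affine is None:
        affine = np.eye(4)
    return Bold4D(values, affine, tr_s=tr_s)


def full_mask(shape, affine=None, label="brain") -> VoxelMask:
    if affine is None:
        affine = np.eye(4)
    return VoxelMask(np.ones(shape, dtype=bool), affine, label)
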