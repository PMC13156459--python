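import numpy as np
import pytest

import nlinvpp as nv


@pytest.fixture(scope="session")
def grid64():
    return nv.Grid2D(64, 64)


@pytest.fixture(scope="session")
def phantom64(grid64):
    return nv.make_phantom(grid64, nv.default_phantom_spec())


@pytest.fixture(scope="session")
def ring_coils64(grid64):
    return nv.make_coils(grid64, nv.CoilLayout(8))


@pytest.fixture(scope="session")
def full_pattern64(grid64):
    return nv.make_pattern(grid64, 1, 1)


@pytest.fixture(scope="session")
def noiseless_kspace64(phantom64, ring_coils64, full_pattern64):
    return nv.sample_kspace(phantom64, ring_coils64, full_pattern64)


@pytest.fixture(scope="session")
def noiseless_recon64(noiseless_kspace64):
    """One shared noiseless full-mask reconstruction (12 steps, defaults)."""
    return nv.nlinv(noiseless_kspace64)


def random_state(grid, nc, seed):
    """Random (image, preconditioned coils) pair for operator tests."""
    rng = np.random.default_rng(seed)

    def rnd(shape):
        return rng.standard_normal(shape) + 1j * rng.standard_normal(shape)

    return (
        nv.ComplexImage(grid, rnd(grid.shape)),
        nv.CoilSet(grid, rnd((nc, *grid.shape)), "preconditioned"),
    )
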