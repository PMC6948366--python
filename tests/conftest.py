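import numpy as np
import pytest

import dbsdiff as dd


@pytest.fixture(scope="session")
def scheme32():
    return dd.make_scheme(32, 800.0)


@pytest.fixture(scope="session")
def scheme8():
    """Small scheme (8 directions + b0) for registration-heavy tests."""
    return dd.make_scheme(8, 800.0)


@pytest.fixture(scope="session")
def study_phantom():
    return dd.build_study_phantom()


@pytest.fixture(scope="session")
def pre_dwi(study_phantom, scheme32):
    return dd.simulate_dwi(study_phantom, scheme32, sigma=5.0, seed=11, session="pre")


def single_tensor_signal(scheme, evals, s0=1000.0, evecs=None):
    """Closed-form single-tensor signal S = S0 exp(−b gᵀDg) for one voxel."""
    evals = np.asarray(evals, dtype=float)
    if evecs is None:
        evecs = np.eye(3)
    D = evecs @ np.diag(evals) @ evecs.T
    quad = np.einsum("ni,ij,nj->n", scheme.bvecs, D, scheme.bvecs)
    return s0 * np.exp(-scheme.bvals * quad)


def single_tensor_volume(scheme, evals, shape=(3, 3, 3), s0=1000.0, evecs=None):
    s = single_tensor_signal(scheme, evals, s0=s0, evecs=evecs)
    signal = np.tile(s, shape + (1,))
    return dd.DWIVolume(
        signal, scheme, (2.0, 2.0, 2.0),
        masks={"brain": np.ones(shape, dtype=bool)},
    )
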