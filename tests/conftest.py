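import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20211)


def random_psd_tensors(n, rng, channels=3):
    """Random per-pixel PSD 2x2 tensors as sums of channel outer products,
    arranged as a 1 x n tensor field."""
    from vagrad import structure_tensor

    grads = rng.normal(size=(1, n, 2, channels))
    return structure_tensor(grads), grads


def tensors_as_matrices(field):
    """Stack a SymTensorField into (n, 2, 2) matrices for np.linalg.eigh."""
    t11 = field.t11.ravel()
    t12 = field.t12.ravel()
    t22 = field.t22.ravel()
    m = np.empty((t11.size, 2, 2))
    m[:, 0, 0] = t11
    m[:, 0, 1] = t12
    m[:, 1, 0] = t12
    m[:, 1, 1] = t22
    return m
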