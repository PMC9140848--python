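import numpy as np
import pytest


def sbs_from_sbn(node_probs: np.ndarray) -> np.ndarray:
    """State-by-state TPM built by explicit enumeration (test-local helper).

    Independent of the package's expansion code: loops over every
    (current, next) state pair and multiplies per-node Bernoulli factors.
    """
    n = node_probs.shape[1]
    T = np.ones((2**n, 2**n))
    for i in range(2**n):
        for v in range(2**n):
            pr = 1.0
            for j in range(n):
                pr *= node_probs[i, j] if (v >> j) & 1 else 1.0 - node_probs[i, j]
            T[i, v] = pr
    return T


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_nonlinear_runs():
    """Three reduced-length runs of the fixed-lag nonlinear model."""
    import phitau as pt

    return pt.simulate(pt.nonlinear_2ch(n_timepoints=4000, n_runs=3, seed=11))
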