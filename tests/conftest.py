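import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def random_binary_graph(rng, n, p=0.4, ensure_edge=True):
    """Symmetric 0/1 adjacency with zero diagonal."""
    a = (rng.random((n, n)) < p).astype(float)
    a = np.triu(a, 1)
    a = a + a.T
    if ensure_edge and a.sum() == 0:
        a[0, 1] = a[1, 0] = 1.0
    return a


def two_cliques(size=3):
    """Two disconnected cliques of the given size."""
    n = 2 * size
    a = np.zeros((n, n))
    for offset in (0, size):
        block = slice(offset, offset + size)
        a[block, block] = 1.0
    np.fill_diagonal(a, 0.0)
    return a


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny deterministic synthetic cohort shared across tests."""
    from restnet import synthetic

    cfg = synthetic.reduced_config(n_subjects_per_group=5, n_timepoints=150, seed=77)
    return cfg, synthetic.sample_cohort(cfg)
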