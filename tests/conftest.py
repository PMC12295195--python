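import numpy as np
import pytest
import scipy.sparse as sp

from spgrn import simulate
from spgrn.datamodel import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def random_norm_matrix(rng):
    """50 genes x 40 units with a dense normalized layer (for oracles)."""
    counts = sp.csr_matrix(rng.integers(0, 40, size=(50, 40)))
    m = ExpressionMatrix(
        genes=np.array([f"G{i:03d}" for i in range(50)], dtype=object),
        units=np.array([f"u{i:02d}" for i in range(40)], dtype=object),
        counts=counts,
    )
    m.normalized = rng.normal(size=(50, 40))
    return m


@pytest.fixture(scope="session")
def small_tissue():
    """One compact simulated tissue shared by read-only tests."""
    cfg = simulate.compact_config(seed=7)
    return simulate.simulate_tissue(cfg), cfg
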