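import numpy as np
import pytest

from hypergrn.data import ExpressionMatrix, Hypergraph
from hypergrn.io_preprocess import build_hypergraph, normalize


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_raw():
    """4 cells x 3 genes raw counts with some zeros."""
    values = np.array([
        [0.0, 2.0, 1.0],
        [3.0, 0.0, 4.0],
        [1.0, 1.0, 0.0],
        [2.0, 5.0, 6.0],
    ])
    return ExpressionMatrix(values, ["c0", "c1", "c2", "c3"],
                            ["g0", "g1", "g2"], stage="raw")


@pytest.fixture
def small_hypergraph(small_raw) -> Hypergraph:
    return build_hypergraph(small_raw, normalize(small_raw))


@pytest.fixture
def random_hypergraph(rng) -> Hypergraph:
    """20 genes x 10 cells, ~70% dense, normalized features."""
    raw = rng.poisson(2.0, size=(10, 20)).astype(float)
    raw[0, :] = 1.0  # no empty cell
    raw[:, 0] = 1.0  # no empty gene
    X = ExpressionMatrix(raw, [f"c{i}" for i in range(10)],
                         [f"g{j}" for j in range(20)], stage="raw")
    return build_hypergraph(X, normalize(X))
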