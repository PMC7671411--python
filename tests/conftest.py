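import numpy as np
import pytest

from scsketch.io import ExpressionMatrix, filter_min_count, normalize_and_log
from scsketch.synthetic import SimSpec, simulate_counts


@pytest.fixture
def small_counts() -> ExpressionMatrix:
    """4x4 integer counts with known zero patterns."""
    values = np.array(
        [
            [5, 0, 2, 0],
            [0, 0, 0, 0],  # all-zero cell
            [1, 0, 3, 1],
            [2, 0, 0, 4],
        ]
    )
    return ExpressionMatrix(values, layer="raw")


@pytest.fixture
def three_cluster_lognorm():
    """300 cells x 200 genes, 3 well-separated groups, lognorm layer."""
    spec = SimSpec(
        n_cells=300,
        n_genes=200,
        group_sizes=(150, 100, 50),
        de_fraction=0.3,
        de_strength=2.0,
        seed=3,
    )
    m, labels = simulate_counts(spec)
    keep = m.values.sum(axis=1) >= 1
    m = filter_min_count(m, 1)
    ln = normalize_and_log(m, 1e4)
    return ln, labels[keep]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
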