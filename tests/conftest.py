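import numpy as np
import pytest

from novagene.data_model import ConditionDesign, ExpressionMatrix
import pandas as pd


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_expr():
    """5 genes x 6 samples with simple structure for exact checks."""
    rng = np.random.default_rng(7)
    values = rng.normal(size=(5, 6))
    return ExpressionMatrix(
        tuple(f"g{i}" for i in range(5)),
        tuple(f"s{j}" for j in range(6)),
        values,
    )


@pytest.fixture
def two_condition_design():
    samples = tuple(f"s{j}" for j in range(6))
    conditions = ("a", "a", "a", "b", "b", "b")
    traits = pd.DataFrame({"flag": [0, 0, 0, 1, 1, 1]}, index=list(samples))
    return ConditionDesign(samples, conditions, traits)


def two_clique_adjacency(n_per: int = 30) -> np.ndarray:
    """Two unit-weight cliques with zero adjacency between them."""
    n = 2 * n_per
    adj = np.zeros((n, n))
    adj[:n_per, :n_per] = 1.0
    adj[n_per:, n_per:] = 1.0
    np.fill_diagonal(adj, 0.0)
    return adj
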