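import numpy as np
import pytest

import rsec


@pytest.fixture
def blobs3():
    """Three well-separated Gaussian blobs in 5 features; returns (data, truth)."""
    rng = np.random.default_rng(42)
    centers = np.array([[0.0] * 5, [30.0] * 5, [-30.0, 30.0, -30.0, 30.0, -30.0]])
    data = np.concatenate(
        [rng.normal(c, 1.0, size=(20, 5)) for c in centers]).T  # features x samples
    truth = np.repeat([1, 2, 3], 20)
    return data, truth


@pytest.fixture
def small_sim():
    """Small simulated expression dataset with 3 crisp clusters."""
    return rsec.simulate_clusters(
        rsec.SimSpec(n=60, G=80, K=3, effect=5.0, seed=7))


@pytest.fixture
def expr_matrix():
    rng = np.random.default_rng(0)
    return rsec.ExpressionMatrix(
        rng.normal(5, 1, size=(10, 6)),
        gene_ids=[f"g{i}" for i in range(10)],
        sample_ids=[f"s{i}" for i in range(6)],
    )
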