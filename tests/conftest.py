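import numpy as np
import pytest

from dlonmf import ExpressionMatrix, generate_planted


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    values = rng.random((6, 5)) * 4.0
    return ExpressionMatrix(
        values,
        gene_ids=[f"g{i}" for i in range(6)],
        sample_ids=[f"s{j}" for j in range(5)],
    )


@pytest.fixture
def planted_small():
    """Noiseless 20x30 dataset with 3 planted factors/clusters."""
    return generate_planted(m=20, n=30, k_true=3, c=3, noise_sd=0.0, seed=7)
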