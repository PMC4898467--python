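import numpy as np
import pytest

from oudiff.types import ExpressionMatrix, InitialDistribution, OUGeneParams


@pytest.fixture
def gene_params():
    """Single-gene OU parameters used across the kernel tests."""
    def make(alpha=1.0, sigma2=2.0, theta=0.0):
        th = np.atleast_1d(theta)
        return OUGeneParams(alpha=[alpha], sigma2=[sigma2], theta=th[None, :])
    return make


@pytest.fixture
def single_gene_init():
    def make(mu0=1.0, var0=0.4):
        return InitialDistribution(mu0=[mu0], var0=[var0])
    return make


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(42)
    values = rng.normal(size=(6, 4))
    return ExpressionMatrix(
        values=values,
        cell_ids=[f"c{i}" for i in range(6)],
        gene_ids=[f"g{j}" for j in range(4)],
    )
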