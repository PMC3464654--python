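import numpy as np
import pytest

from betaeb import BetaConfig, ExpressionData, HyperParams, gene_scale_table, simulate_lnn
from betaeb.simulator import SimConfig


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_clean_sim():
    """A small clean LNN dataset (T=300, n=10+10) shared across tests."""
    return simulate_lnn(SimConfig(T=300, n1=10, n2=10, seed=7))


@pytest.fixture(scope="session")
def small_clean_scales(small_clean_sim):
    return gene_scale_table(small_clean_sim.data, BetaConfig())


@pytest.fixture
def tiny_data():
    """A deterministic 6-gene, 4+4-sample dataset for exact-value tests."""
    rng = np.random.default_rng(99)
    values = 2.0 + rng.standard_normal((6, 8)) * 0.4
    labels = np.array([1, 1, 1, 1, 2, 2, 2, 2])
    return ExpressionData(values=values, group_labels=labels)


@pytest.fixture
def theta():
    return HyperParams(mu0=2.0, tau0_sq=3.0, p1=0.05)
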