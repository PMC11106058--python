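import numpy as np
import pytest

import bayesnetreg as bnr


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small theoretical-simulation dataset shared by structural tests."""
    cfg = bnr.SimulationConfig(V=5, k=3, n=30, mu=1.6, pi=0.5)
    return bnr.simulate_dataset(cfg, np.random.default_rng(11))


def random_symmetric(V, rng, nonneg=False):
    A = rng.normal(size=(V, V))
    if nonneg:
        A = np.abs(A)
    return (A + A.T) / 2.0
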