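import numpy as np
import pytest

import shapeggen as sg


@pytest.fixture(scope="session")
def sg_base():
    """One full-scale benchmark instance (seed 0), shared across tests."""
    return sg.generate(sg.preset("SG-Base"))


@pytest.fixture(scope="session")
def small_ds():
    """A small, class-balanced instance for fast model/metric tests.

    Higher connection probability compensates for the quadratic drop in
    subgraph-pair counts at 100 subgraphs, keeping both classes populated.
    """
    cfg = sg.preset("SG-Base").replace(
        num_subgraphs=100, connection_prob=0.05, seed=3
    )
    return sg.generate(cfg)


@pytest.fixture(scope="session")
def small_model(small_ds):
    return sg.train(small_ds, sg.PredictorConfig(epochs=300, seed=1))


@pytest.fixture(scope="session")
def tiny_ds():
    """A ~200-node instance for brute-force oracle comparisons."""
    cfg = sg.preset("SG-Base").replace(
        num_subgraphs=20, connection_prob=0.2, seed=7
    )
    return sg.generate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
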