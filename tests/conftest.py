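import numpy as np
import pandas as pd
import pytest

import coregflux as cf
from coregflux.benchmark import make_benchmark


@pytest.fixture(scope="session")
def chain_model():
    return cf.make_toy_model("chain")


@pytest.fixture(scope="session")
def branch_model():
    return cf.make_toy_model("branch")


@pytest.fixture(scope="session")
def diauxic_model():
    return cf.make_toy_model("diauxic")


@pytest.fixture(scope="session")
def benchmark():
    """Standard planted end-to-end benchmark (built once per session)."""
    return make_benchmark(seed=0)


@pytest.fixture
def small_network():
    net = cf.RegulatoryNetwork()
    for gene in ("a1", "a2", "a3"):
        net.add_edge("TF1", gene, +1)
    for gene in ("r1", "r2"):
        net.add_edge("TF1", gene, -1)
    net.add_edge("TF2", "a1", -1)
    net.add_edge("TF2", "b1", +1)
    net.add_edge("TF2", "b2", +1)
    net.add_edge("TF2", "r1", -1)
    return net


@pytest.fixture
def small_expression(small_network):
    rng = np.random.default_rng(123)
    genes = sorted(small_network.targets | small_network.regulators)
    return pd.DataFrame(
        rng.normal(size=(len(genes), 6)),
        index=genes,
        columns=[f"S{k}" for k in range(6)],
    )
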