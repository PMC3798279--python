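import numpy as np
import pytest

from merlin import (ExpressionMatrix, Hyperparameters, ModuleAssignment,
                    RegulatoryNetwork, RegulatorSet, simulate_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_expr(rng):
    """Six genes x 8 samples; A drives B (x2+1) and C (-1x), D/E/F noise."""
    m = 8
    a = rng.normal(size=m)
    values = np.stack([
        a,
        2.0 * a + 1.0,
        -a + 0.5,
        rng.normal(size=m),
        rng.normal(size=m),
        rng.normal(size=m),
    ])
    return ExpressionMatrix(["A", "B", "C", "D", "E", "F"],
                            [f"s{i}" for i in range(m)], values)


@pytest.fixture()
def toy_modules():
    return ModuleAssignment({"A": 1, "B": 1, "C": 1, "D": 2, "E": 2, "F": 2})


@pytest.fixture()
def toy_network():
    net = RegulatoryNetwork()
    net.add_edge("A", "B", 2.0)
    net.add_edge("A", "C", -1.0)
    net.add_edge("D", "E", 0.5)
    return net


@pytest.fixture(scope="session")
def net100():
    """A NET100-style simulated instance: 100 genes, 11 regulators,
    100 knockout samples, q = 0.8, noise 0.1."""
    truth, expr = simulate_dataset(n_genes=100, regulator_fraction=0.11,
                                   q=0.8, noise_sd=0.1, seed=7)
    return truth, expr


@pytest.fixture()
def default_hyper():
    return Hyperparameters()
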