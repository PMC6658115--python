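import numpy as np
import pandas as pd
import pytest

from coexgwas.data_io import ExpressionMatrix
from coexgwas.synthetic import SimulationConfig, simulate_expression, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A complete synthetic study with GWAS effects planted on module 1's
    eQTL SNPs (shared across tests; treat as read-only)."""
    return simulate_study(SimulationConfig(seed=11), target_module=1)


@pytest.fixture(scope="session")
def planted_expression():
    """Expression with 4 planted 50-gene modules plus 100 background genes."""
    cfg = SimulationConfig(seed=5, n_samples=100)
    expr, labels, _ = simulate_expression(cfg)
    return expr, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_expr(values, tissue=""):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"g{i}" for i in range(values.shape[0])],
            columns=[f"s{j}" for j in range(values.shape[1])],
        ),
        tissue=tissue,
    )
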