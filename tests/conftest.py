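import numpy as np
import pytest

from helpers import std_cols


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_regression(rng):
    """Well-conditioned n > p problem with two real effects."""
    n, p = 120, 8
    X = std_cols(rng.standard_normal((n, p)))
    beta = np.zeros(p)
    beta[0], beta[3] = 0.6, -0.4
    y = X @ beta + rng.standard_normal(n)
    y -= y.mean()
    return X, y, beta


@pytest.fixture(scope="session")
def sim1_dataset():
    """One replicate of the baseline power-study design (600 x 5, beta=0.15)."""
    from lassogwas.simdata import ScenarioConfig, make_scenario

    G, pheno = make_scenario(ScenarioConfig(p0=0, seed=4242))
    y = pheno.values - pheno.values.mean()
    return G, y, pheno
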