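import numpy as np
import pytest

from cca.model import CompositeModelSpec, PopulationModelParams
from cca.simulation import population_model


def equicorr(k: int, r: float) -> np.ndarray:
    m = np.full((k, k), r)
    np.fill_diagonal(m, 1.0)
    return m


@pytest.fixture(scope="session")
def two_block_spec():
    return CompositeModelSpec({"c1": ["x11", "x12", "x13"], "c2": ["x21", "x22", "x23"]})


@pytest.fixture(scope="session")
def fig2_spec():
    """One composite of two indicators plus two free observed variables."""
    return CompositeModelSpec({"c": ["x1", "x2"]}, free_variables=["y", "z"])


@pytest.fixture(scope="session")
def model1():
    return population_model(1)


@pytest.fixture(scope="session")
def model4():
    return population_model(4)


@pytest.fixture(scope="session")
def model1_params(model1):
    return model1.params


def random_pd(rng: np.random.Generator, k: int) -> np.ndarray:
    a = rng.standard_normal((k, k + 2))
    m = a @ a.T / (k + 2)
    return m + 1e-3 * np.eye(k)


def random_correlation(rng: np.random.Generator, k: int) -> np.ndarray:
    m = random_pd(rng, k)
    d = 1.0 / np.sqrt(np.diag(m))
    return m * np.outer(d, d)
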