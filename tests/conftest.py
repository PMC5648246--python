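import numpy as np
import pytest

from barcodekit.distances import DistanceMatrix, distance_matrix
from barcodekit.synthetic import SimulationSpec, generate_dataset, generate_worked_toy


@pytest.fixture(scope="session")
def toy():
    """8-sequence worked data set plus exact per-pair substitution counts."""
    return generate_worked_toy()


@pytest.fixture(scope="session")
def toy_ds(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_dm(toy_ds):
    return distance_matrix(toy_ds, model="K2P")


@pytest.fixture(scope="session")
def default_sim():
    """One library generated under the default study conditions."""
    ds, truth = generate_dataset(SimulationSpec(seed=11))
    return ds, truth


@pytest.fixture(scope="session")
def default_dm(default_sim):
    return distance_matrix(default_sim[0], model="K2P")


def random_distance_matrix(rng, n, tie_prob=0.3, scale=0.05):
    """Small random symmetric matrix, with ties made likely by value quantization."""
    vals = rng.uniform(0, scale, size=(n, n))
    if rng.random() < tie_prob:
        vals = np.round(vals, 3)  # coarse grid forces exact ties
    d = np.triu(vals, k=1)
    d = d + d.T
    ids = [f"s{i}" for i in range(n)]
    return DistanceMatrix(ids=ids, d=d, model="p", comparable_sites=np.full((n, n), 658))
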