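import numpy as np
import pytest

from spcanet import DataMatrix, GaussianJointModel, worked_fixture
from spcanet.netgen import GoldStandard, SimulationSpec, default_ids, gold_to_precision, simulate_expression


def random_correlation(dim: int, rng: np.random.Generator, *, max_cond: float = 1e4) -> np.ndarray:
    """A random well-conditioned correlation matrix (rejection sampled)."""
    while True:
        a = rng.standard_normal((dim, dim + 2))
        s = a @ a.T
        d = np.sqrt(np.diag(s))
        c = s / d[:, None] / d[None, :]
        if np.linalg.cond(c) < max_cond:
            return (c + c.T) / 2.0


@pytest.fixture(scope="session")
def fixture_instance():
    """The pinned 5-gene chain/fork dataset with its gold standard."""
    return worked_fixture()


@pytest.fixture(scope="session")
def chain_data():
    """X - Z - Y chain: X and Y dependent marginally, independent given Z.

    Variables are ordered (X, Z, Y): the non-edge is the pair (0, 2) with
    separator {1}.
    """
    gold = GoldStandard(3, {(0, 1), (1, 2)}, default_ids(3))
    spec = SimulationSpec(
        n=3, m=10_000, target_edges=2, density=None,
        topology="erdos_renyi", partial_correlation_range=(0.5, 0.6), seed=11,
    )
    omega = gold_to_precision(gold, spec)
    return simulate_expression(omega, 10_000, seed=12, ids=gold.ids)


@pytest.fixture
def model_pair():
    """Factory for a 2-variable Gaussian model at a given correlation."""

    def make(rho: float) -> GaussianJointModel:
        return GaussianJointModel(
            (0, 1), np.zeros(2), np.array([[1.0, rho], [rho, 1.0]])
        )

    return make


@pytest.fixture
def iid_data():
    rng = np.random.default_rng(99)
    return DataMatrix(rng.standard_normal((8, 1000)), tuple(f"V{i}" for i in range(8)))
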