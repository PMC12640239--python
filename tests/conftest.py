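import numpy as np
import pytest

from metnetbench.inference import NONNEGATIVE, SIGNED, AssociationMatrix
from metnetbench.synthetic_data import (
    AdjacencyMatrix,
    MetabolicNetwork,
    Reaction,
    SampleMatrix,
    generate_network,
    network_to_adjacency,
    simulate_samples,
)


def names(n: int) -> tuple[str, ...]:
    return tuple(f"M{i:02d}" for i in range(n))


def assoc_from(values, family=NONNEGATIVE) -> AssociationMatrix:
    values = np.asarray(values, dtype=float)
    return AssociationMatrix(names(values.shape[0]), values, family)


def adjacency_from(values) -> AdjacencyMatrix:
    values = np.asarray(values)
    return AdjacencyMatrix(names(values.shape[0]), values)


def random_adjacency(n: int, p: float, rng: np.random.Generator) -> AdjacencyMatrix:
    upper = rng.random((n, n)) < p
    a = np.triu(upper, k=1)
    return adjacency_from((a | a.T).astype(int))


@pytest.fixture(scope="session")
def small_network() -> MetabolicNetwork:
    return generate_network(n_nodes=10, n_extra_edges=2, mm_fraction=0.5, seed=42)


@pytest.fixture(scope="session")
def small_samples(small_network) -> SampleMatrix:
    return simulate_samples(small_network, n_samples=60, seed=42)


@pytest.fixture(scope="session")
def small_adjacency(small_network) -> AdjacencyMatrix:
    return network_to_adjacency(small_network)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def reversible_pair(k1: float = 2.0, k2: float = 0.5) -> MetabolicNetwork:
    """Closed two-species system A <-> B with mass-action rates k1, k2."""
    return MetabolicNetwork(
        nodes=("A", "B"),
        reactions=(
            Reaction("fwd", ("A",), ("B",), "mass_action", {"k": k1}),
            Reaction("rev", ("B",), ("A",), "mass_action", {"k": k2}),
        ),
    )
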