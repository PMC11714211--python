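import numpy as np
import pytest

from netscreen.funcsim import GoDag
from netscreen.interactome import InteractomeGraph
from netscreen.synthetic import FixtureSpec, make_all


@pytest.fixture
def path3() -> InteractomeGraph:
    """Path graph a - b - c."""
    return InteractomeGraph([("a", "b"), ("b", "c")])


@pytest.fixture
def tiny_dag() -> GoDag:
    """One-namespace DAG: root r with is_a children a and b (w = 0.8)."""
    return GoDag(
        {"r": "BP", "a": "BP", "b": "BP"},
        [("a", "r", "is_a"), ("b", "r", "is_a")],
    )


def random_graph(n: int, rng: np.random.Generator, p: float = 0.08) -> InteractomeGraph:
    """Connected-ish random graph: a random spanning path plus G(n,p) edges."""
    nodes = [f"n{i:03d}" for i in range(n)]
    order = rng.permutation(n)
    edges = {(nodes[min(a, b)], nodes[max(a, b)]) for a, b in zip(order, order[1:])}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.add((nodes[i], nodes[j]))
    return InteractomeGraph(sorted(edges))


@pytest.fixture(scope="session")
def small_fixture():
    """Shared synthetic study system (1000 nodes, 25-gene planted module)."""
    return make_all(FixtureSpec(master_seed=11))
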