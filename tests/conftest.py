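import itertools

import numpy as np
import pytest

from netwarp import Network, fig2_graph


@pytest.fixture
def fig2():
    return fig2_graph()


@pytest.fixture
def triangle():
    return Network(["a", "b", "c"], [("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def path3():
    """3-node path a-b-c."""
    return Network(["a", "b", "c"], [("a", "b"), ("b", "c")])


def complete_graph(k: int) -> Network:
    ids = [f"n{i}" for i in range(k)]
    return Network(ids, list(itertools.combinations(ids, 2)))


def random_connected_network(n: int, p: float, rng: np.random.Generator) -> Network:
    """Erdős–Rényi graph patched to be connected via a random spanning chain."""
    ids = [f"g{i}" for i in range(n)]
    edges = set()
    order = rng.permutation(n)
    for a, b in zip(order[:-1], order[1:]):
        edges.add((ids[min(a, b)], ids[max(a, b)]))
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(len(iu)) < p
    for a, b in zip(iu[mask], ju[mask]):
        edges.add((ids[a], ids[b]))
    return Network(ids, sorted(edges))
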