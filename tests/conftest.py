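import numpy as np
import pytest

from asymweb.io import FoodWeb
from asymweb.synthgen import fixtures


@pytest.fixture(scope="session")
def webs():
    """The canonical small fixture webs (path-3, star-4, cycle-4, ...)."""
    return fixtures()


def random_web(rng: np.random.Generator, max_nodes: int = 8) -> FoodWeb:
    """A small random undirected web with at least one edge (for oracles)."""
    while True:
        n = int(rng.integers(2, max_nodes + 1))
        p = float(rng.uniform(0.2, 0.9))
        labels = [f"v{i}" for i in range(n)]
        edges = [
            (labels[i], labels[j])
            for i in range(n)
            for j in range(i + 1, n)
            if rng.random() < p
        ]
        if edges:
            return FoodWeb.from_edges("random", edges, nodes=labels)


def walk_effect_oracle(web: FoodWeb, m: int) -> np.ndarray:
    """Brute-force m-step effects: enumerate every length-m walk explicitly.

    Each walk contributes the product of one-step effects 1/degree(receiver)
    along its steps.  Independent of the matrix-power implementation.
    """
    nodes = web.nodes
    idx = {v: k for k, v in enumerate(nodes)}
    neighbors = {v: [] for v in nodes}
    for u, v in web.undirected_edges:
        neighbors[u].append(v)
        neighbors[v].append(u)
    degree = {v: len(nbs) for v, nbs in neighbors.items()}
    vals = np.zeros((len(nodes), len(nodes)))

    def extend(tail: str, start: str, prod: float, remaining: int) -> None:
        if remaining == 0:
            vals[idx[start], idx[tail]] += prod
            return
        for nb in neighbors[tail]:
            extend(nb, start, prod / degree[nb], remaining - 1)

    for s in nodes:
        extend(s, s, 1.0, m)
    return vals


def ti_oracle(web: FoodWeb, n: int) -> np.ndarray:
    """Brute-force TI^n (unnormalized, mean-aggregated, zero diagonal)."""
    acc = sum(walk_effect_oracle(web, m) for m in range(1, n + 1)) / n
    np.fill_diagonal(acc, 0.0)
    return acc
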