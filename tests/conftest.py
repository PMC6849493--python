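import itertools

import numpy as np
import pytest

from netattack.attack import AttackConfig, targeted_attack
from netattack.network import SymptomNetwork


def star_network(n_leaves: int) -> SymptomNetwork:
    """Hub 'h' connected to n unit-weight leaves."""
    leaves = [f"l{i:02d}" for i in range(n_leaves)]
    return SymptomNetwork.from_edges(["h"] + leaves, [("h", l, 1.0) for l in leaves])


@pytest.fixture
def star5() -> SymptomNetwork:
    return star_network(5)


@pytest.fixture
def path3() -> SymptomNetwork:
    return SymptomNetwork.from_edges(["a", "b", "c"], [("a", "b", 1.0), ("b", "c", 1.0)])


@pytest.fixture
def k4() -> SymptomNetwork:
    labels = ["a", "b", "c", "d"]
    edges = [(u, v, 1.0) for u, v in itertools.combinations(labels, 2)]
    return SymptomNetwork.from_edges(labels, edges)


@pytest.fixture
def barbell7() -> SymptomNetwork:
    """Two triangles joined by a single bridge edge c-d."""
    edges = [("a", "b", 1.0), ("a", "c", 1.0), ("b", "c", 1.0),
             ("d", "e", 1.0), ("d", "f", 1.0), ("e", "f", 1.0),
             ("c", "d", 1.0)]
    return SymptomNetwork.from_edges(list("abcdef"), edges)


def exhaustive_outcomes(net: SymptomNetwork, fn) -> list[float]:
    """fn(trajectory) evaluated over every removal order (oracle for small n)."""
    out = []
    for perm in itertools.permutations(net.labels):
        traj = targeted_attack(net, order=perm, config=AttackConfig())
        out.append(fn(traj))
    return out


def random_graph(n: int, density: float, seed: int) -> SymptomNetwork:
    rng = np.random.default_rng(seed)
    adj = np.zeros((n, n))
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    m = max(1, int(round(density * len(pairs))))
    for k in rng.choice(len(pairs), size=m, replace=False):
        i, j = pairs[k]
        w = rng.uniform(0.2, 1.0) * (1 if rng.random() < 0.9 else -1)
        adj[i, j] = adj[j, i] = w
    return SymptomNetwork(tuple(f"S{i:02d}" for i in range(n)), adj)
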