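"""Weighted symptom-network container.

A psychopathological network is an undirected, signed-weighted graph whose
nodes are symptoms and whose edges are estimated pairwise interactions
(typically regularized partial correlations).  :class:`SymptomNetwork` is the
in-memory object every other module consumes: it wraps a labeled, symmetric,
zero-diagonal adjacency matrix and offers cheap subnetwork extraction, which
the attack engine relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = ["SymptomNetwork"]


@dataclass(frozen=True)
class SymptomNetwork:
    """Undirected signed-weighted graph over labeled symptoms.

    Parameters
    ----------
    labels
        Unique symptom names, one per node.
    adjacency
        Square symmetric matrix with zero diagonal; a nonzero entry
        ``adjacency[i, j]`` is the signed weight of the edge i–j.
    """

    labels: tuple[str, ...]
    adjacency: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=float)
        object.__setattr__(self, "adjacency", adj)
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError(f"adjacency must be square, got shape {adj.shape}")
        if len(self.labels) != adj.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {adj.shape[0]} nodes"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate symptom labels")
        if not np.all(np.isfinite(adj)):
            raise ValueError("adjacency contains non-finite weights")
        if not np.allclose(adj, adj.T, atol=1e-10):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(adj) != 0):
            raise ValueError("adjacency diagonal must be zero (no self-loops)")

    # -- basic properties -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, k=1)))

    @property
    def density(self) -> float:
        n = self.n_nodes
        if n < 2:
            return 0.0
        return self.n_edges / (n * (n - 1) / 2)

    def index(self, node: str) -> int:
        try:
            return self.labels.index(node)
        except ValueError:
            raise KeyError(f"unknown symptom {node!r}") from None

    def __contains__(self, node: str) -> bool:
        return node in self.labels

    # -- derived views -----------------------------------------------------

    def subnetwork(self, keep: Sequence[int] | Sequence[str]) -> "SymptomNetwork":
        """Induced subgraph on ``keep`` (indices or labels), order preserved."""
        idx = [self.index(k) if isinstance(k, str) else int(k) for k in keep]
        sub = self.adjacency[np.ix_(idx, idx)]
        return SymptomNetwork(tuple(self.labels[i] for i in idx), sub)

    def to_networkx(self, absolute: bool = False) -> nx.Graph:
        """networkx view; ``absolute=True`` replaces weights by |w|."""
        g = nx.Graph()
        g.add_nodes_from(self.labels)
        rows, cols = np.nonzero(np.triu(self.adjacency, k=1))
        for i, j in zip(rows, cols):
            w = self.adjacency[i, j]
            g.add_edge(self.labels[i], self.labels[j], weight=abs(w) if absolute else w)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "SymptomNetwork":
        labels = tuple(str(v) for v in g.nodes())
        adj = nx.to_numpy_array(g, nodelist=list(g.nodes()), weight="weight")
        np.fill_diagonal(adj, 0.0)
        return cls(labels, adj)

    @classmethod
    def from_edges(
        cls,
        labels: Iterable[str],
        edges: Iterable[tuple[str, str, float]],
    ) -> "SymptomNetwork":
        labels = tuple(labels)
        pos = {l: i for i, l in enumerate(labels)}
        adj = np.zeros((len(labels), len(labels)))
        for u, v, w in edges:
            adj[pos[u], pos[v]] = w
            adj[pos[v], pos[u]] = w
        return cls(labels, adj)
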