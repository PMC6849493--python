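"""Symptom ranking measures: degree, strength, modular overlap and bridgeness.

Central symptoms are scored by degree (count of connections) and strength
(sum of absolute edge weights).  Bridge symptoms are scored from an
overlapping module decomposition: *modular overlap* is the effective number
of modules a symptom is assigned to (its trans-modular role) and *modular
bridgeness* the effective number of modules its connections reach (its
inter-modular role), both via the inverse participation ratio 1 / sum(p^2).

The module backend produces the two required outputs — a fuzzy node-module
membership matrix and a module connection profile — from a deterministic
greedy-modularity base partition followed by random-walk membership
smoothing:

    q(i, .) <- (1 - alpha) * onehot(base(i)) + alpha * sum_j P(i, j) q(j, .)

with P the |w| row-normalized adjacency, iterated to a fixed point.  The
connection profile is c(i, m) proportional to sum_j |w_ij| q(j, m).  The
backend is pluggable behind the :class:`ModuleAssignment` contract; no
numerical equivalence with any particular published overlapping-community
tool is claimed, only ordinal fidelity on planted fixtures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import networkx as nx
import numpy as np

from .network import SymptomNetwork

__all__ = [
    "Measure",
    "ModuleAssignment",
    "RankedOrder",
    "degree",
    "strength",
    "degrees",
    "strengths",
    "detect_modules",
    "effective_number",
    "modular_overlap",
    "modular_bridgeness",
    "measure_values",
    "rank_nodes",
]

log = logging.getLogger(__name__)

Measure = Literal["degree", "strength", "bridgeness", "overlap"]
MEASURES: tuple[Measure, ...] = ("degree", "strength", "bridgeness", "overlap")


# --------------------------------------------------------------------------
# Centrality
# --------------------------------------------------------------------------


def degrees(net: SymptomNetwork) -> np.ndarray:
    """Number of nonzero-weight connections per node."""
    return (net.adjacency != 0).sum(axis=1).astype(float)


def strengths(net: SymptomNetwork) -> np.ndarray:
    """Sum of absolute incident edge weights per node."""
    return np.abs(net.adjacency).sum(axis=1)


def degree(net: SymptomNetwork, node: str) -> int:
    return int(degrees(net)[net.index(node)])


def strength(net: SymptomNetwork, node: str) -> float:
    return float(strengths(net)[net.index(node)])


# --------------------------------------------------------------------------
# Overlapping modules
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ModuleAssignment:
    """Fuzzy module decomposition of a network.

    ``membership`` (q) and ``connection_profile`` (c) are node-by-module
    row-stochastic matrices; ``base_partition`` holds the hard module index
    each node was anchored to.
    """

    labels: tuple[str, ...]
    membership: np.ndarray = field(repr=False)
    connection_profile: np.ndarray = field(repr=False)
    base_partition: np.ndarray = field(repr=False)
    alpha: float = 0.5
    iterations: int = 0
    tol: float = 1e-6

    @property
    def n_modules(self) -> int:
        return self.membership.shape[1]

    def index(self, node: str) -> int:
        try:
            return self.labels.index(node)
        except ValueError:
            raise KeyError(f"unknown symptom {node!r}") from None


def _base_partition(net: SymptomNetwork) -> np.ndarray:
    """Hard partition by greedy modularity maximization on |w|.

    Communities are re-indexed by their smallest node index so module ids are
    stable and independent of networkx's internal ordering.
    """
    g = net.to_networkx(absolute=True)
    communities = nx.community.greedy_modularity_communities(g, weight="weight")
    communities = sorted(
        (sorted(net.index(v) for v in com) for com in communities),
        key=lambda com: com[0],
    )
    part = np.empty(net.n_nodes, dtype=int)
    for m, com in enumerate(communities):
        for i in com:
            part[i] = m
    return part


def detect_modules(
    net: SymptomNetwork,
    alpha: float = 0.5,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> ModuleAssignment:
    """Overlapping module decomposition (see module docstring).

    Raises ``ValueError`` on an edgeless network; callers should then treat
    every node as its own singleton module.
    """
    if net.n_edges == 0:
        raise ValueError(
            "edgeless network: no module structure; treat all nodes as singleton modules"
        )
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    base = _base_partition(net)
    n, n_mod = net.n_nodes, int(base.max()) + 1
    onehot = np.zeros((n, n_mod))
    onehot[np.arange(n), base] = 1.0

    w = np.abs(net.adjacency)
    row_sums = w.sum(axis=1)
    P = np.where(row_sums[:, None] > 0, w / np.maximum(row_sums, 1e-300)[:, None], 0.0)
    isolated = row_sums == 0
    # isolated nodes keep their one-hot membership via a self-transition
    for i in np.where(isolated)[0]:
        P[i, i] = 1.0

    q = onehot.copy()
    iterations = 0
    for iterations in range(1, max_iter + 1):
        q_new = (1 - alpha) * onehot + alpha * (P @ q)
        delta = np.abs(q_new - q).max()
        q = q_new
        if delta < tol:
            break

    raw = w @ q
    conn_sums = raw.sum(axis=1)
    profile = np.where(
        conn_sums[:, None] > 0, raw / np.maximum(conn_sums, 1e-300)[:, None], 0.0
    )
    # isolated nodes: profile defined as their own membership anchor
    profile[isolated] = onehot[isolated]
    if isolated.any():
        log.info(
            "%d isolated node(s): connection profile set to the base module anchor",
            int(isolated.sum()),
        )
    return ModuleAssignment(
        labels=net.labels,
        membership=q,
        connection_profile=profile,
        base_partition=base,
        alpha=alpha,
        iterations=iterations,
        tol=tol,
    )


def effective_number(distribution: Sequence[float] | np.ndarray) -> float:
    """Inverse participation ratio 1 / sum(p^2) of a probability vector."""
    p = np.asarray(distribution, dtype=float)
    if p.ndim != 1 or (p < -1e-12).any():
        raise ValueError("need a nonnegative vector")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError(f"distribution sums to {p.sum():.6f}, expected 1")
    return float(1.0 / np.sum(p**2))


def modular_overlap(assignment: ModuleAssignment, node: str) -> float:
    """Effective number of modules the node is assigned to (trans-modular role)."""
    return effective_number(assignment.membership[assignment.index(node)])


def modular_bridgeness(assignment: ModuleAssignment, node: str) -> float:
    """Effective number of modules the node's connections reach (inter-modular
    role); an isolated node scores 1 by convention."""
    i = assignment.index(node)
    row = assignment.connection_profile[i]
    if row.sum() == 0:  # pragma: no cover - profiles are always normalized
        return 1.0
    return effective_number(row)


# --------------------------------------------------------------------------
# Ranking
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RankedOrder:
    """Descending removal order of all nodes under one measure."""

    measure: str
    order: tuple[str, ...]
    values: tuple[float, ...]
    tie_rule: str = "label"

    def __post_init__(self) -> None:
        if len(set(self.order)) != len(self.order):
            raise ValueError("order is not a permutation")
        vals = np.asarray(self.values)
        if len(vals) and np.any(np.diff(vals) > 1e-12):
            raise ValueError("measure values along the order must be non-increasing")


def measure_values(
    net: SymptomNetwork,
    measure: Measure,
    assignment: ModuleAssignment | None = None,
) -> np.ndarray:
    """Vector of the requested measure for every node, in label order."""
    if measure == "degree":
        return degrees(net)
    if measure == "strength":
        return strengths(net)
    if measure in ("bridgeness", "overlap"):
        if assignment is None:
            raise ValueError(f"{measure} ranking requires a ModuleAssignment")
        mat = (
            assignment.membership
            if measure == "overlap"
            else assignment.connection_profile
        )
        sq = np.sum(mat**2, axis=1)
        return 1.0 / np.maximum(sq, 1e-300)
    raise ValueError(f"unknown measure {measure!r}")


def rank_nodes(
    net: SymptomNetwork,
    measure: Measure,
    assignment: ModuleAssignment | None = None,
    seed: int | None = None,
) -> RankedOrder:
    """Rank all nodes by descending measure value.

    Ties are broken by ascending label (deterministic default) or uniformly
    at random when ``seed`` is given.
    """
    values = measure_values(net, measure, assignment)
    labels = list(net.labels)
    if seed is None:
        idx = sorted(range(len(labels)), key=lambda i: (-values[i], labels[i]))
        tie_rule = "label"
    else:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(labels))
        idx = sorted(perm, key=lambda i: -values[i])
        tie_rule = f"random(seed={seed})"
    return RankedOrder(
        measure=measure,
        order=tuple(labels[i] for i in idx),
        values=tuple(float(values[i]) for i in idx),
        tie_rule=tie_rule,
    )
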