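"""Synthetic ground-truth models and network ensembles.

The study design re-analyzes a heterogeneous sample of published symptom
networks (5–120 nodes, densities roughly 0.07–0.86, up to 5 components).
Because those adjacency matrices are not redistributable, this module
generates networks with the same statistical footprint, plus ground-truth
graphical models (Gaussian precision matrices, Ising models) for testing
network re-estimation, and planted modular fixtures with known overlapping
and bridging nodes for testing the bridge measures.

All generators take explicit integer seeds and never touch global RNG state.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .network import SymptomNetwork

__all__ = [
    "PrecisionModel",
    "IsingModel",
    "PlantedModularNetwork",
    "EnsembleSpec",
    "gen_precision_model",
    "sample_gaussian",
    "gen_ising_model",
    "sample_ising",
    "gen_planted_modules",
    "gen_network_ensemble",
    "save_ensemble",
]


# --------------------------------------------------------------------------
# Gaussian graphical ground truth
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PrecisionModel:
    """Ground-truth Gaussian graphical model.

    ``precision`` is symmetric positive definite; ``partials`` holds the
    implied partial correlations rho_ij = -kappa_ij / sqrt(kappa_ii kappa_jj)
    with zero diagonal; ``support`` is the set of (i, j), i < j, pairs with a
    nonzero partial.
    """

    precision: np.ndarray = field(repr=False)
    partials: np.ndarray = field(repr=False)
    support: frozenset[tuple[int, int]]

    @property
    def p(self) -> int:
        return self.precision.shape[0]

    def covariance(self) -> np.ndarray:
        return np.linalg.inv(self.precision)


def _random_support(
    p: int, density: float, rng: np.random.Generator
) -> list[tuple[int, int]]:
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    m = int(round(density * len(pairs)))
    if m == 0:
        return []
    chosen = rng.choice(len(pairs), size=m, replace=False)
    return [pairs[k] for k in sorted(chosen)]


def gen_precision_model(
    p: int,
    density: float,
    seed: int,
    weight_scale: float = 0.35,
    positive_fraction: float = 0.9,
    max_condition: float = 1e4,
) -> PrecisionModel:
    """Draw a sparse precision matrix with a uniformly random edge support.

    Off-diagonal entries are placed on ``round(density * p(p-1)/2)`` uniformly
    chosen pairs; the matrix is made positive definite by diagonal loading on
    a deterministic retry ladder until the smallest eigenvalue is positive and
    the condition number is at most ``max_condition``.  ``positive_fraction``
    controls the sign mix of the implied partial correlations (partial
    correlation sign is the negated precision sign).
    """
    if p < 3:
        raise ValueError("need at least 3 variables")
    if not 0 <= density <= 1:
        raise ValueError("density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    support = _random_support(p, density, rng)

    K = np.eye(p)
    for i, j in support:
        mag = rng.uniform(0.5, 1.0) * weight_scale
        sign = 1.0 if rng.random() < positive_fraction else -1.0
        K[i, j] = K[j, i] = -sign * mag  # negative precision -> positive partial

    # Deterministic retry ladder: load the diagonal until PD and well
    # conditioned.  Loading only rescales magnitudes; support is untouched.
    for load in (0.0, 0.1, 0.25, 0.5, 1.0, 2.0, 5.0, 10.0):
        cand = K + load * np.eye(p)
        eig = np.linalg.eigvalsh(cand)
        if eig[0] > 1e-8 and eig[-1] / eig[0] <= max_condition:
            K = cand
            break
    else:  # pragma: no cover - ladder covers any unit-diagonal draw
        raise RuntimeError("diagonal loading failed to produce a usable precision")

    d = np.sqrt(np.diag(K))
    partials = -K / np.outer(d, d)
    np.fill_diagonal(partials, 0.0)
    return PrecisionModel(K, partials, frozenset(support))


def sample_gaussian(model: PrecisionModel, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` observations from N(0, precision^-1); rows are samples."""
    if n < 1:
        raise ValueError("need at least one observation")
    eig = np.linalg.eigvalsh(model.precision)
    if eig[0] <= 0:
        raise ValueError("precision matrix is singular or indefinite")
    rng = np.random.default_rng(seed)
    cov = model.covariance()
    return rng.multivariate_normal(np.zeros(model.p), cov, size=n, method="cholesky")


# --------------------------------------------------------------------------
# Ising ground truth
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class IsingModel:
    """Pairwise binary (0/1) graphical model: thresholds + symmetric couplings."""

    thresholds: np.ndarray = field(repr=False)
    couplings: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.couplings, dtype=float)
        if not np.allclose(c, c.T):
            raise ValueError("couplings must be symmetric")
        if not (np.isfinite(c).all() and np.isfinite(self.thresholds).all()):
            raise ValueError("non-finite Ising parameters")

    @property
    def p(self) -> int:
        return len(self.thresholds)


def gen_ising_model(
    p: int,
    density: float,
    coupling_scale: float = 1.0,
    seed: int = 0,
    positive_fraction: float = 0.9,
) -> IsingModel:
    """Random Ising model: couplings on a uniform support, magnitudes near
    ``coupling_scale``, thresholds drawn negative so marginal activation
    probabilities stay away from 0 and 1."""
    if p < 3:
        raise ValueError("need at least 3 nodes")
    rng = np.random.default_rng(seed)
    support = _random_support(p, density, rng)
    J = np.zeros((p, p))
    for i, j in support:
        mag = rng.uniform(0.75, 1.25) * coupling_scale
        sign = 1.0 if rng.random() < positive_fraction else -1.0
        J[i, j] = J[j, i] = sign * mag
    thresholds = rng.uniform(-1.5, -0.5, size=p)
    return IsingModel(thresholds, J)


def sample_ising(
    model: IsingModel,
    n: int,
    burnin: int = 200,
    thin: int = 2,
    seed: int = 0,
) -> np.ndarray:
    """Gibbs-sample ``n`` rows of 0/1 states.

    Full-conditional activation probability of node i is
    sigmoid(threshold_i + sum_j J_ij x_j).  One sweep updates every node once
    in index order; rows are recorded every ``thin`` sweeps after ``burnin``
    sweeps.
    """
    if n < 1:
        raise ValueError("need at least one sample")
    if burnin < 0 or thin < 1:
        raise ValueError("burnin must be >= 0 and thin >= 1")
    rng = np.random.default_rng(seed)
    p = model.p
    x = (rng.random(p) < 0.5).astype(float)
    out = np.empty((n, p))
    total_sweeps = burnin + n * thin
    u = rng.random((total_sweeps, p))
    row = 0
    for sweep in range(total_sweeps):
        for i in range(p):
            field_i = model.thresholds[i] + model.couplings[i] @ x
            prob = 1.0 / (1.0 + math.exp(-field_i))
            x[i] = 1.0 if u[sweep, i] < prob else 0.0
        if sweep >= burnin and (sweep - burnin) % thin == thin - 1:
            out[row] = x
            row += 1
    return out


# --------------------------------------------------------------------------
# Planted modular fixtures
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedModularNetwork:
    """Network with known module structure.

    ``true_modules`` may overlap; ``true_overlap_nodes`` are exactly the
    nodes in two modules, and ``true_bridge_nodes`` are single-membership
    endpoints of inter-module edges.
    """

    network: SymptomNetwork
    true_modules: tuple[frozenset[str], ...]
    true_overlap_nodes: frozenset[str]
    true_bridge_nodes: frozenset[str]


def gen_planted_modules(
    clique_sizes: list[int],
    shared_nodes: int = 0,
    bridge_edges: int = 0,
    weight: float = 1.0,
    seed: int = 0,
) -> PlantedModularNetwork:
    """Build fully connected modules with optional overlapping and bridging nodes.

    Each of the ``shared_nodes`` nodes belongs to two (cyclically consecutive)
    modules and carries all within-module edges of both; each of the
    ``bridge_edges`` single edges joins two modules through otherwise
    single-membership endpoints.  Module count, sizes and the requested
    counts must be feasible (e.g. at least two modules for sharing/bridging).
    """
    m = len(clique_sizes)
    if m < 1 or any(s < 3 for s in clique_sizes):
        raise ValueError("each module needs at least 3 nodes")
    if shared_nodes < 0 or bridge_edges < 0:
        raise ValueError("counts must be nonnegative")
    if (shared_nodes or bridge_edges) and m < 2:
        raise ValueError("sharing or bridging requires at least two modules")
    if weight <= 0:
        raise ValueError("weight must be positive")
    rng = np.random.default_rng(seed)

    module_pairs = [(k, (k + 1) % m) for k in range(m)] if m > 2 else [(0, 1)]
    shared_assignment = [module_pairs[k % len(module_pairs)] for k in range(shared_nodes)]
    for k in range(m):
        if sum(1 for pair in shared_assignment if k in pair) >= clique_sizes[k]:
            raise ValueError(f"module {k} too small for the requested shared nodes")

    members: list[set[int]] = [set() for _ in range(m)]
    next_id = 0
    for pair in shared_assignment:
        for k in pair:
            members[k].add(next_id)
        next_id += 1
    overlap_ids = set(range(next_id))
    for k, size in enumerate(clique_sizes):
        while len(members[k]) < size:
            members[k].add(next_id)
            next_id += 1

    n = next_id
    labels = tuple(f"S{idx:02d}" for idx in range(n))
    adj = np.zeros((n, n))
    for mem in members:
        for i in mem:
            for j in mem:
                if i < j:
                    adj[i, j] = adj[j, i] = weight

    bridge_ids: set[int] = set()
    candidates = []
    for a in range(m):
        for b in range(a + 1, m):
            for i in sorted(members[a] - overlap_ids):
                for j in sorted(members[b] - overlap_ids):
                    if adj[i, j] == 0:
                        candidates.append((i, j))
    if bridge_edges > len(candidates):
        raise ValueError("not enough disjoint endpoint pairs for bridge edges")
    if bridge_edges:
        chosen = rng.choice(len(candidates), size=bridge_edges, replace=False)
        for k in sorted(chosen):
            i, j = candidates[k]
            adj[i, j] = adj[j, i] = weight
            bridge_ids.update((i, j))

    return PlantedModularNetwork(
        network=SymptomNetwork(labels, adj),
        true_modules=tuple(frozenset(labels[i] for i in mem) for mem in members),
        true_overlap_nodes=frozenset(labels[i] for i in overlap_ids),
        true_bridge_nodes=frozenset(labels[i] for i in bridge_ids),
    )


# --------------------------------------------------------------------------
# Network ensembles
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class EnsembleSpec:
    """Recipe for an ensemble of signed-weighted networks.

    Defaults mirror the descriptives of the 51-network study sample: node
    counts from a right-skewed (log-normal) distribution truncated to
    [5, 120] with mean ~23 and SD ~21, densities uniform on
    [0.067, 0.861], edge-weight magnitudes in (0, 1] with a 90/10
    positive/negative sign mix.
    """

    k: int = 51
    node_range: tuple[int, int] = (5, 120)
    density_range: tuple[float, float] = (0.067, 0.861)
    weight_magnitude_range: tuple[float, float] = (0.05, 1.0)
    positive_fraction: float = 0.9
    lognormal_mu: float = 2.75
    lognormal_sigma: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be at least 1")
        if self.node_range[0] > self.node_range[1] or self.node_range[0] < 2:
            raise ValueError("invalid node_range")
        lo, hi = self.density_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("density_range must lie in (0, 1] and be ordered")


def _draw_node_count(spec: EnsembleSpec, rng: np.random.Generator) -> int:
    lo, hi = spec.node_range
    if lo == hi:
        return lo
    for _ in range(1000):
        n = int(round(rng.lognormal(spec.lognormal_mu, spec.lognormal_sigma)))
        if lo <= n <= hi:
            return n
    return int(rng.integers(lo, hi + 1))  # pragma: no cover - fallback


def gen_network_ensemble(spec: EnsembleSpec) -> list[SymptomNetwork]:
    """Generate ``spec.k`` networks; connectedness is not forced (published
    symptom networks show up to 5 components)."""
    rng = np.random.default_rng(spec.seed)
    nets = []
    for _ in range(spec.k):
        n = _draw_node_count(spec, rng)
        density = rng.uniform(*spec.density_range)
        support = _random_support(n, density, rng)
        adj = np.zeros((n, n))
        for i, j in support:
            mag = rng.uniform(*spec.weight_magnitude_range)
            sign = 1.0 if rng.random() < spec.positive_fraction else -1.0
            adj[i, j] = adj[j, i] = sign * mag
        labels = tuple(f"S{i:03d}" for i in range(n))
        nets.append(SymptomNetwork(labels, adj))
    return nets


def save_ensemble(
    nets: list[SymptomNetwork], out_dir: str, spec: EnsembleSpec | None = None
) -> list[str]:
    """Write each network as adjacency CSV plus a JSON sidecar of descriptives."""
    from .io import write_network

    os.makedirs(out_dir, exist_ok=True)
    paths = []
    meta = []
    for i, net in enumerate(nets):
        path = os.path.join(out_dir, f"network_{i:03d}.csv")
        write_network(net, path)
        paths.append(path)
        meta.append(
            {"file": os.path.basename(path), "nodes": net.n_nodes,
             "edges": net.n_edges, "density": net.density}
        )
    sidecar: dict = {"networks": meta}
    if spec is not None:
        sidecar["spec"] = {
            "k": spec.k, "node_range": list(spec.node_range),
            "density_range": list(spec.density_range),
            "weight_magnitude_range": list(spec.weight_magnitude_range),
            "positive_fraction": spec.positive_fraction, "seed": spec.seed,
        }
    with open(os.path.join(out_dir, "ensemble.json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return paths
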