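"""Generators: precision models, Ising models, planted modules, ensembles."""

import itertools

import numpy as np
import pytest

from netattack.synthetic import (
    EnsembleSpec,
    IsingModel,
    gen_ising_model,
    gen_network_ensemble,
    gen_planted_modules,
    gen_precision_model,
    sample_gaussian,
    sample_ising,
)


class TestPrecisionModel:
    def test_zero_density_gives_diagonal_partials(self):
        m = gen_precision_model(3, density=0.0, seed=1)
        assert np.all(m.partials == 0)
        assert m.support == frozenset()

    def test_support_size_matches_density(self):
        m = gen_precision_model(10, density=0.2, seed=7)
        assert len(m.support) == round(0.2 * 45)

    def test_positive_definite(self):
        m = gen_precision_model(15, density=0.2, seed=3)
        assert np.linalg.eigvalsh(m.precision)[0] > 0

    def test_partials_consistent_with_precision(self):
        m = gen_precision_model(8, density=0.4, seed=5)
        K = m.precision
        d = np.sqrt(np.diag(K))
        expected = -K / np.outer(d, d)
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(m.partials, expected)
        assert np.abs(m.partials).max() <= 1

    @pytest.mark.parametrize("seed", range(25))
    def test_realized_density_within_one_edge(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(4, 25))
        density = float(rng.uniform(0.05, 0.9))
        m = gen_precision_model(p, density, seed=seed)
        target = density * p * (p - 1) / 2
        assert abs(len(m.support) - target) <= 1

    def test_rejects_tiny_p(self):
        with pytest.raises(ValueError):
            gen_precision_model(2, 0.5, seed=0)


class TestGaussianSampler:
    def test_shape_single_row(self):
        m = gen_precision_model(4, 0.3, seed=0)
        assert sample_gaussian(m, 1, seed=0).shape == (1, 4)

    def test_identity_precision_uncorrelated(self):
        m = gen_precision_model(5, 0.0, seed=0)
        X = sample_gaussian(m, 5000, seed=1)
        C = np.corrcoef(X, rowvar=False)
        off = C[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_pairwise_correlation_matches_model(self):
        # 3-node model; compare sample correlations to cov = precision^-1
        m = gen_precision_model(3, 1.0, seed=2)
        cov = m.covariance()
        d = np.sqrt(np.diag(cov))
        rho_model = cov / np.outer(d, d)
        X = sample_gaussian(m, 10000, seed=2)
        C = np.corrcoef(X, rowvar=False)
        assert np.abs(C - rho_model).max() < 0.03

    def test_chain_model_conditional_independence(self):
        # chain 0-1-2: empirical partial correlation of the 0,2 pair -> 0
        K = np.eye(3)
        K[0, 1] = K[1, 0] = -0.4
        K[1, 2] = K[2, 1] = -0.4
        from netattack.synthetic import PrecisionModel

        model = PrecisionModel(K, np.zeros((3, 3)), frozenset({(0, 1), (1, 2)}))
        n = 20000
        X = sample_gaussian(model, n, seed=3)
        Khat = np.linalg.inv(np.cov(X, rowvar=False))
        pc = -Khat[0, 2] / np.sqrt(Khat[0, 0] * Khat[2, 2])
        assert abs(pc) < 3 / np.sqrt(n)

    def test_deterministic(self):
        m = gen_precision_model(5, 0.4, seed=4)
        np.testing.assert_array_equal(
            sample_gaussian(m, 10, seed=9), sample_gaussian(m, 10, seed=9)
        )


class TestIsing:
    def test_zero_density_no_couplings(self):
        m = gen_ising_model(5, density=0.0, seed=1)
        assert np.all(m.couplings == 0)

    def test_support_size(self):
        m = gen_ising_model(10, density=0.3, seed=1)
        nz = np.count_nonzero(np.triu(m.couplings))
        assert abs(nz - round(0.3 * 45)) <= 1

    def test_deterministic_model(self):
        a, b = (gen_ising_model(6, 0.4, seed=3) for _ in range(2))
        np.testing.assert_array_equal(a.couplings, b.couplings)
        np.testing.assert_array_equal(a.thresholds, b.thresholds)

    def test_sampler_single_row_binary(self):
        m = gen_ising_model(4, 0.5, seed=0)
        X = sample_ising(m, 1, burnin=10, seed=0)
        assert X.shape == (1, 4)
        assert set(np.unique(X)) <= {0.0, 1.0}

    def test_independent_nodes_half_activation(self):
        m = IsingModel(np.zeros(4), np.zeros((4, 4)))
        X = sample_ising(m, 4000, burnin=50, thin=1, seed=1)
        assert np.abs(X.mean(axis=0) - 0.5).max() < 0.03

    def test_two_node_matches_boltzmann_enumeration(self):
        # exact distribution over the 4 states of a 2-node model
        t = np.array([-0.5, 0.3])
        J = np.array([[0.0, 1.2], [1.2, 0.0]])
        m = IsingModel(t, J)
        states = list(itertools.product([0, 1], repeat=2))
        energies = [t @ s + J[0, 1] * s[0] * s[1] for s in map(np.array, states)]
        probs = np.exp(energies) / np.sum(np.exp(energies))
        n = 20000
        X = sample_ising(m, n, burnin=100, thin=2, seed=2)
        for s, p_exact in zip(states, probs):
            freq = np.mean((X == s).all(axis=1))
            se = np.sqrt(p_exact * (1 - p_exact) / n)
            assert abs(freq - p_exact) < 5 * se + 0.01

    def test_positive_coupling_raises_agreement(self):
        base = IsingModel(np.zeros(2), np.zeros((2, 2)))
        coupled = IsingModel(np.zeros(2), np.array([[0.0, 2.0], [2.0, 0.0]]))
        Xb = sample_ising(base, 4000, burnin=50, thin=1, seed=3)
        Xc = sample_ising(coupled, 4000, burnin=50, thin=1, seed=3)
        agree = lambda X: np.mean(X[:, 0] == X[:, 1])  # noqa: E731
        assert agree(Xc) > agree(Xb) + 0.1


class TestPlantedModules:
    def test_two_cliques_one_shared(self):
        fx = gen_planted_modules([6, 6], shared_nodes=1, seed=0)
        net = fx.network
        assert net.n_nodes == 11
        shared = next(iter(fx.true_overlap_nodes))
        from netattack.measures import degree

        assert degree(net, shared) == 10
        assert len(fx.true_modules) == 2

    def test_single_bridge_edge(self):
        fx = gen_planted_modules([5, 5], shared_nodes=0, bridge_edges=1, seed=1)
        inter = 0
        net = fx.network
        mods = [set(m) for m in fx.true_modules]
        for i in range(net.n_nodes):
            for j in range(i + 1, net.n_nodes):
                if net.adjacency[i, j] != 0:
                    li, lj = net.labels[i], net.labels[j]
                    if not any(li in m and lj in m for m in mods):
                        inter += 1
                        assert {li, lj} == set(fx.true_bridge_nodes)
        assert inter == 1

    def test_disjoint_cliques_components(self):
        fx = gen_planted_modules([4, 4, 4], seed=2)
        from netattack.attack import n_components

        assert n_components(fx.network) == 3

    def test_infeasible_counts_error(self):
        with pytest.raises(ValueError):
            gen_planted_modules([4], shared_nodes=1, seed=0)
        with pytest.raises(ValueError):
            gen_planted_modules([3, 3], bridge_edges=100, seed=0)


class TestEnsemble:
    def test_ranges_respected(self):
        spec = EnsembleSpec(k=51, node_range=(5, 120), density_range=(0.067, 0.861), seed=11)
        nets = gen_network_ensemble(spec)
        assert len(nets) == 51
        for net in nets:
            assert 5 <= net.n_nodes <= 120
            target = net.density * net.n_nodes * (net.n_nodes - 1) / 2
            assert net.n_edges == round(target)  # density realized by construction
            adj = net.adjacency
            assert np.allclose(adj, adj.T)
            assert np.all(np.diag(adj) == 0)
            mags = np.abs(adj[adj != 0])
            assert mags.min() > 0 and mags.max() <= 1

    def test_complete_graph_edge_case(self):
        spec = EnsembleSpec(k=1, node_range=(5, 5), density_range=(1.0, 1.0), seed=0)
        (net,) = gen_network_ensemble(spec)
        assert net.n_nodes == 5 and net.n_edges == 10

    def test_deterministic(self):
        spec = EnsembleSpec(k=5, seed=42)
        a, b = gen_network_ensemble(spec), gen_network_ensemble(spec)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.adjacency, y.adjacency)

    def test_node_count_distribution_right_skewed(self):
        spec = EnsembleSpec(k=200, seed=5)
        sizes = np.array([n.n_nodes for n in gen_network_ensemble(spec)])
        # log-normal target: mean ~23, SD ~21, median well below the mean
        assert 15 < sizes.mean() < 32
        assert np.median(sizes) < sizes.mean()
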