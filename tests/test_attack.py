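"""Attack engine: state metrics, targeted and random trajectories."""

import itertools

import numpy as np
import pytest

from conftest import exhaustive_outcomes, random_graph, star_network
from netattack.attack import (
    AttackConfig,
    avg_path_length,
    connectivity,
    n_components,
    random_attack,
    targeted_attack,
)
from netattack.impact import impact_magnitude
from netattack.measures import rank_nodes
from netattack.network import SymptomNetwork


class TestStateMetrics:
    def test_connectivity_counts_and_weights(self, k4):
        assert connectivity(k4) == 6
        net = SymptomNetwork.from_edges(["a", "b", "c"], [("a", "b", 0.5), ("b", "c", -0.3)])
        assert connectivity(net, weighted=True) == pytest.approx(0.8)
        assert connectivity(SymptomNetwork(("a",), np.zeros((1, 1)))) == 0

    def test_components(self, star5):
        assert n_components(star5) == 1
        assert n_components(SymptomNetwork(tuple("abcd"), np.zeros((4, 4)))) == 4
        two_edges = SymptomNetwork.from_edges(
            ["a", "b", "c", "d"], [("a", "b", 1.0), ("c", "d", 1.0)]
        )
        assert n_components(two_edges) == 2

    def test_avg_path_length_path3(self, path3):
        # ordered pair distances: 1,1,2 (x2) -> mean 4/3
        assert avg_path_length(path3) == pytest.approx(4 / 3)

    def test_avg_path_length_complete(self, k4):
        assert avg_path_length(k4) == pytest.approx(1.0)

    def test_disconnected_pairs_excluded(self):
        net = SymptomNetwork.from_edges(
            ["a", "b", "c", "d"], [("a", "b", 1.0), ("c", "d", 1.0)]
        )
        assert avg_path_length(net) == pytest.approx(1.0)

    def test_edgeless_is_nan(self):
        assert np.isnan(avg_path_length(SymptomNetwork(("a", "b"), np.zeros((2, 2)))))

    def test_inverse_weight_distances(self):
        net = SymptomNetwork.from_edges(["a", "b"], [("a", "b", 0.5)])
        assert avg_path_length(net, "inverse_weight") == pytest.approx(2.0)


class TestTargetedAttack:
    def test_star_degree_components_trajectory(self, star5):
        traj = targeted_attack(star5, order=rank_nodes(star5, "degree"))
        assert list(traj.components[:5]) == [1, 5, 4, 3, 2]
        assert len(traj.components) == 6  # N states
        assert len(traj.removal_order) == 5

    def test_complete_graph_connectivity_trajectory(self, k4):
        traj = targeted_attack(k4, order=list(k4.labels))
        assert list(traj.connectivity) == [6, 3, 1, 0]

    def test_two_node_trajectory_length(self):
        net = SymptomNetwork.from_edges(["a", "b"], [("a", "b", 1.0)])
        traj = targeted_attack(net, order=["a", "b"])
        assert len(traj.connectivity) == 2
        assert len(traj.removal_order) == 1

    def test_non_permutation_rejected(self, star5):
        with pytest.raises(ValueError):
            targeted_attack(star5, order=["h", "h", "l00", "l01", "l02", "l03"])

    def test_connectivity_nonincreasing_and_component_bounds(self):
        for seed in range(5):
            net = random_graph(12, 0.3, seed)
            order = rank_nodes(net, "strength")
            traj = targeted_attack(net, order=order)
            assert np.all(np.diff(traj.connectivity) <= 1e-12)
            n = net.n_nodes
            for step in range(n):
                assert 1 <= traj.components[step] <= n - step

    def test_trajectory_states_match_direct_metrics(self):
        # per-step fast-kernel values equal independent whole-network metrics
        net = random_graph(10, 0.4, seed=3)
        order = rank_nodes(net, "degree")
        traj = targeted_attack(net, order=order)
        remaining = list(net.labels)
        for step in range(net.n_nodes):
            if step > 0:
                remaining.remove(traj.removal_order[step - 1])
            sub = net.subnetwork(remaining)
            assert traj.connectivity[step] == connectivity(sub)
            assert traj.components[step] == n_components(sub)
            if sub.n_edges and sub.n_nodes > 1:
                assert traj.path_length[step] == pytest.approx(avg_path_length(sub))

    def test_weighted_connectivity_mode(self):
        net = SymptomNetwork.from_edges(["a", "b", "c"], [("a", "b", 0.5), ("b", "c", -0.3)])
        traj = targeted_attack(
            net, order=["b", "a", "c"], config=AttackConfig(weighted_connectivity=True)
        )
        assert traj.connectivity[0] == pytest.approx(0.8)
        assert traj.connectivity[1] == pytest.approx(0.0)

    def test_recalculated_mode_star(self, star5):
        traj = targeted_attack(star5, mode="recalculated", measure="degree")
        assert traj.removal_order[0] == "h"
        assert traj.mode == "recalculated"

    def test_recalculated_differs_when_initial_ranking_stale(self):
        # hub chain: after removing the first hub, initial-order attacks keep
        # removing its former neighbors while the cascade re-targets
        net = SymptomNetwork.from_edges(
            ["h1", "a", "b", "c", "h2", "x", "y", "z"],
            [("h1", n, 1.0) for n in ["a", "b", "c", "h2"]]
            + [("h2", n, 1.0) for n in ["x", "y", "z"]],
        )
        init = targeted_attack(net, order=rank_nodes(net, "degree"))
        casc = targeted_attack(net, mode="recalculated", measure="degree")
        assert casc.removal_order[:2] == ("h1", "h2")
        assert impact_magnitude(casc, "components") >= impact_magnitude(init, "components")


class TestRandomAttack:
    def test_deterministic_replicates(self, star5):
        a = random_attack(star5, n_sims=20, seed=9)
        b = random_attack(star5, n_sims=20, seed=9)
        for x, y in zip(a, b):
            assert x.removal_order == y.removal_order
            np.testing.assert_array_equal(x.components, y.components)

    def test_substreams_stable_under_nsims_change(self, star5):
        a = random_attack(star5, n_sims=5, seed=9)
        b = random_attack(star5, n_sims=20, seed=9)
        for x, y in zip(a, b[:5]):
            assert x.removal_order == y.removal_order

    def test_single_replicate_valid(self, path3):
        (traj,) = random_attack(path3, n_sims=1, seed=0)
        assert len(traj.connectivity) == 3

    def test_path3_peak_components_enumeration(self, path3):
        # oracle: 2 of 6 orders remove the middle node first -> peak 2
        peaks = exhaustive_outcomes(path3, lambda t: t.components.max())
        assert sorted(set(peaks)) == [1, 2]
        assert np.mean(peaks) == pytest.approx(4 / 3)
        sim = random_attack(path3, n_sims=600, seed=4)
        sim_mean = np.mean([t.components.max() for t in sim])
        se = np.std([t.components.max() for t in sim]) / np.sqrt(600)
        assert abs(sim_mean - 4 / 3) < 3 * se + 1e-12

    def test_degree_attack_beats_random_on_scale_free(self):
        import networkx as nx

        # classic robustness ordering on preferential-attachment graphs
        deg_first, rand_first = [], []
        for seed in range(5):
            g = nx.barabasi_albert_graph(60, 2, seed=seed)
            net = SymptomNetwork(
                tuple(f"S{i:02d}" for i in range(60)), nx.to_numpy_array(g)
            )
            td = targeted_attack(net, order=rank_nodes(net, "degree"))
            peak = td.components.max()
            deg_first.append(int(np.argmax(td.components >= peak)))
            reps = random_attack(net, n_sims=20, seed=seed)
            rand_first.append(
                np.mean([np.argmax(t.components >= t.components.max()) for t in reps])
            )
        assert np.mean(deg_first) < np.mean(rand_first)
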