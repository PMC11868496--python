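"""SPIKE-distance, synchronization score, network mapping, Louvain."""

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from organoidmea import (
    ChannelMeta, NO_COMMUNITY, SpikeTrain, SyncMatrix, SyncParams,
    assign_communities, build_network, export_network_map,
    louvain_communities, modularity, network_metrics, read_network_map,
    spike_distance, sync_matrix, sync_score,
)
from oracles import (
    max_modularity_exhaustive, modularity_matrix, reference_spike_distance,
    riemann_spike_distance,
)


def _train(times, T=10.0, channel=0):
    return SpikeTrain(channel=channel, times=np.asarray(times, float),
                      duration=T)


class TestSpikeDistance:
    def test_identical_trains_give_exact_zero(self):
        t = _train([0.3, 0.7, 4.2, 9.1])
        assert spike_distance(t, t) == 0.0

    def test_toy_pair_matches_dense_riemann(self):
        x1, x2 = np.array([0.3, 0.7]), np.array([0.35, 0.75])
        D = spike_distance(x1, x2, 1.0)
        assert D == pytest.approx(riemann_spike_distance(x1, x2, 1.0),
                                  rel=1e-6)

    def test_symmetry_and_positivity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x1 = np.sort(rng.uniform(0, 10, rng.integers(1, 30)))
            x2 = np.sort(rng.uniform(0, 10, rng.integers(1, 30)))
            d_ab = spike_distance(x1, x2, 10.0)
            d_ba = spike_distance(x2, x1, 10.0)
            assert d_ab == pytest.approx(d_ba, abs=1e-14)
            assert d_ab > 0.0

    def test_matches_independent_reference_implementation(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x1 = np.sort(rng.uniform(0, 50, rng.poisson(80)))
            x2 = np.sort(rng.uniform(0, 50, rng.poisson(80)))
            D = spike_distance(x1, x2, 50.0)
            assert D == pytest.approx(
                reference_spike_distance(x1, x2, 50.0), rel=1e-11)

    def test_empty_train_signalled(self):
        with pytest.raises(ValueError):
            spike_distance(np.array([]), np.array([1.0]), 10.0)

    def test_duration_mismatch_signalled(self):
        with pytest.raises(ValueError):
            spike_distance(_train([1.0], T=10.0), _train([1.0], T=20.0))


class TestSyncScore:
    def test_identical_trains_score_one(self):
        t = _train(np.linspace(0.5, 9.5, 40))
        assert sync_score(t, t, SyncParams(n_baseline=50, seed=0)) == 1.0

    def test_scores_stay_in_unit_interval(self):
        rng = np.random.default_rng(2)
        p = SyncParams(n_baseline=100, seed=3)
        for _ in range(10):
            t1 = _train(np.sort(rng.uniform(0, 10, 30)))
            t2 = _train(np.sort(rng.uniform(0, 10, 30)))
            assert 0.0 <= sync_score(t1, t2, p) <= 1.0

    def test_independent_uniform_trains_score_near_zero(self):
        scores = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            t1 = _train(np.sort(rng.uniform(0, 10, 100)))
            t2 = _train(np.sort(rng.uniform(0, 10, 100)))
            scores.append(sync_score(t1, t2,
                                     SyncParams(n_baseline=300, seed=seed)))
        assert abs(np.mean(scores)) <= 0.1

    def test_tighter_jitter_never_lowers_mean_score(self):
        p = SyncParams(n_baseline=150, seed=0)
        means = []
        for jitter in (0.001, 0.02, 0.3):
            scores = []
            for seed in range(6):
                rng = np.random.default_rng(seed)
                mother = np.sort(rng.uniform(0, 20, 60))
                t1 = _train(mother, T=20.0)
                shifted = np.clip(
                    mother + rng.normal(0, jitter, mother.size), 0, 20)
                t2 = _train(np.sort(shifted), T=20.0)
                scores.append(sync_score(t1, t2, p))
            means.append(np.mean(scores))
        assert means[0] >= means[1] >= means[2]

    def test_inactive_pair_signalled(self):
        p = SyncParams(min_spikes_active=5)
        with pytest.raises(ValueError):
            sync_score(_train([1.0, 2.0]), _train(np.linspace(1, 9, 20)), p)


class TestNetworkConstruction:
    def _matrix(self, scores, ids):
        return SyncMatrix(scores=np.asarray(scores, float), active=ids)

    def test_zero_scores_give_edgeless_graph(self):
        sm = self._matrix(np.eye(3), [0, 1, 2])
        g = build_network(sm, None, SyncParams())
        assert g.number_of_nodes() == 3
        assert g.number_of_edges() == 0

    def test_threshold_boundary_edge_retained(self):
        s = np.eye(2)
        s[0, 1] = s[1, 0] = 0.5
        g = build_network(self._matrix(s, [0, 1]), None, SyncParams())
        assert g.has_edge(0, 1)
        assert g[0][1]["weight"] == 0.5

    def test_planted_blocks_give_two_components(self):
        n = 8
        s = np.full((n, n), 0.1)
        for block in (range(0, 4), range(4, 8)):
            for i in block:
                for j in block:
                    s[i, j] = 0.8
        np.fill_diagonal(s, 1.0)
        g = build_network(self._matrix(s, list(range(n))), None, SyncParams())
        comps = sorted(map(sorted, nx.connected_components(g)))
        assert comps == [[0, 1, 2, 3], [4, 5, 6, 7]]

    def test_single_active_channel_gives_empty_matrix(self):
        trains = [_train(np.linspace(1, 9, 30), channel=0),
                  _train([1.0], channel=1)]  # below activity minimum
        sm = sync_matrix(trains, SyncParams(n_baseline=20, seed=0))
        assert sm.active == []
        assert sm.scores.shape == (0, 0)

    def test_sync_matrix_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(4)
        trains = [_train(np.sort(rng.uniform(0, 10, 40)), channel=c)
                  for c in range(4)]
        sm = sync_matrix(trains, SyncParams(n_baseline=50, seed=1))
        assert sm.active == [0, 1, 2, 3]
        assert np.allclose(sm.scores, sm.scores.T)
        assert np.allclose(np.diag(sm.scores), 1.0)


class TestLouvain:
    def _two_cliques(self):
        g = nx.Graph()
        for base in (0, 4):
            for i in range(base, base + 4):
                for j in range(i + 1, base + 4):
                    g.add_edge(i, j, weight=1.0)
        g.add_edge(0, 4, weight=1.0)
        return g

    def test_two_cliques_partitioned_exactly(self):
        g = self._two_cliques()
        res = louvain_communities(g, seed=0)
        groups = {}
        for node, lab in res.labels.items():
            groups.setdefault(lab, set()).add(node)
        assert set(map(frozenset, groups.values())) == {
            frozenset({0, 1, 2, 3}), frozenset({4, 5, 6, 7})}

    def test_two_cliques_reach_exhaustive_optimum(self):
        g = self._two_cliques()
        W = nx.to_numpy_array(g, nodelist=sorted(g), weight="weight")
        q_opt, p_opt = max_modularity_exhaustive(W)
        res = louvain_communities(g, seed=0)
        assert res.modularity == pytest.approx(q_opt, abs=1e-12)
        assert sorted(map(sorted, p_opt)) == [[0, 1, 2, 3], [4, 5, 6, 7]]

    def test_complete_graph_single_community(self):
        g = nx.complete_graph(6)
        nx.set_edge_attributes(g, 1.0, "weight")
        res = louvain_communities(g, seed=1)
        assert len({lab for lab in res.labels.values()}) == 1
        assert set(res.labels.values()) == {0}

    def test_empty_edge_set_no_communities(self):
        g = nx.empty_graph(5)
        res = louvain_communities(g, seed=0)
        assert all(lab == NO_COMMUNITY for lab in res.labels.values())
        assert res.modularity is None

    def test_planted_three_communities_recovered(self):
        aris = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n, k = 12, 3
            truth = np.repeat(np.arange(k), n // k)
            s = np.where(truth[:, None] == truth[None, :],
                         rng.uniform(0.6, 0.9, (n, n)),
                         rng.uniform(0.05, 0.3, (n, n)))
            s = (s + s.T) / 2
            np.fill_diagonal(s, 1.0)
            g = build_network(SyncMatrix(scores=s, active=list(range(n))),
                              None, SyncParams())
            res = louvain_communities(g, seed=seed)
            aris.append(adjusted_rand_score(
                truth, [res.labels[i] for i in range(n)]))
        assert np.mean(aris) >= 0.9

    def test_modularity_agrees_with_matrix_oracle(self):
        rng = np.random.default_rng(5)
        g = nx.gnp_random_graph(7, 0.5, seed=3)
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(0.1, 1.0))
        W = nx.to_numpy_array(g, nodelist=range(7), weight="weight")
        partition = [{0, 1, 2}, {3, 4}, {5, 6}]
        assert modularity(g, partition) == pytest.approx(
            modularity_matrix(W, [[0, 1, 2], [3, 4], [5, 6]]), abs=1e-12)


class TestNetworkMetrics:
    def test_triangle_hand_counts(self):
        g = nx.Graph()
        for u, v in ((0, 1), (1, 2), (0, 2)):
            g.add_edge(u, v, weight=0.8)
        assign_communities(g, louvain_communities(g, seed=0))
        m = network_metrics(g)
        assert m.avg_degree == 2.0
        assert m.total_edges == 3
        assert m.n_connected_nodes == 3
        assert m.n_communities == 1
        assert m.n_nodes_no_community == 0
        assert m.max_community_size == 3

    def test_empty_graph_all_zero(self):
        g = nx.empty_graph(4)
        assign_communities(g, louvain_communities(g, seed=0))
        m = network_metrics(g)
        assert m.total_edges == 0
        assert m.avg_degree == 0.0
        assert m.n_communities == 0
        assert m.n_nodes_no_community == 4

    def test_edge_degree_identity(self):
        rng = np.random.default_rng(6)
        for seed in range(5):
            g = nx.gnp_random_graph(10, 0.4, seed=seed)
            for u, v in g.edges:
                g[u][v]["weight"] = float(rng.uniform(0.5, 1.0))
            assign_communities(g, louvain_communities(g, seed=seed))
            m = network_metrics(g)
            assert m.total_edges == sum(d for _, d in g.degree()) / 2


class TestGraphExport:
    def test_roundtrip_preserves_structure_and_labels(self, tmp_path):
        channels = [ChannelMeta(id=i, x=10.0 * i, y=5.0, height=50.0 * (i + 1))
                    for i in range(4)]
        s = np.eye(4)
        s[0, 1] = s[1, 0] = 0.9
        s[1, 2] = s[2, 1] = 0.7
        s[0, 2] = s[2, 0] = 0.6
        g = build_network(SyncMatrix(scores=s, active=[0, 1, 2, 3]),
                          channels, SyncParams())
        assign_communities(g, louvain_communities(g, seed=0))
        path = tmp_path / "net.graphml"
        export_network_map(g, path)
        back = read_network_map(path)
        assert sorted(back.nodes) == [0, 1, 2, 3]
        assert sorted(back.edges) == sorted(g.edges)
        for n in g.nodes:
            assert back.nodes[n]["height"] == g.nodes[n]["height"]
            assert back.nodes[n]["community"] == g.nodes[n]["community"]
        # node 3 is isolated: "none" community must survive the round trip
        assert back.nodes[3]["community"] == NO_COMMUNITY
        for u, v in g.edges:
            assert back[u][v]["weight"] == pytest.approx(g[u][v]["weight"])
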