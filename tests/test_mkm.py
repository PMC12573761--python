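import numpy as np
import pytest

from kinmap.mkm import (NOISE, EmptyGraphError, MKMGraph, MKMNode,
                        build_mkm, cnn_cluster, enumerate_pathways,
                        partition_by_chi)

from .oracles import (brute_force_cnn, exhaustive_increasing_paths,
                      same_partition)


class TestPartitionByChi:
    def test_three_intervals_known_assignment(self):
        part = partition_by_chi(np.array([0.1, 0.5, 0.9]), 3)
        np.testing.assert_array_equal(part.assignment, [0, 1, 2])

    def test_chi_one_goes_to_last_interval(self):
        part = partition_by_chi(np.array([0.0, 1.0]), 4)
        np.testing.assert_array_equal(part.assignment, [0, 3])

    def test_uniform_chi_fills_intervals_evenly(self):
        chi = np.random.default_rng(0).uniform(0, 1, 10_000)
        part = partition_by_chi(chi, 5)
        counts = np.bincount(part.assignment, minlength=5)
        np.testing.assert_allclose(counts, 2000, rtol=0.1)

    def test_boundaries_cover_unit_interval(self):
        part = partition_by_chi(np.array([0.2, 0.8]), 7)
        assert part.boundaries[0] == 0.0 and part.boundaries[-1] == 1.0
        assert np.all(np.diff(part.boundaries) > 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            partition_by_chi(np.array([0.5, 1.2]), 3)
        with pytest.raises(ValueError):
            partition_by_chi(np.array([0.5]), 1)


class TestCnnCluster:
    def test_identical_states_one_cluster_theta_zero(self):
        pts = np.zeros((10, 2))
        cs = cnn_cluster(pts, epsilon=0.5, theta=0)
        assert cs.n_clusters == 1
        assert np.all(cs.labels == 0)

    def test_two_separated_blobs(self):
        rng = np.random.default_rng(1)
        blob_a = rng.normal(0, 0.1, (20, 2))
        blob_b = rng.normal(0, 0.1, (20, 2)) + [10, 0]
        cs = cnn_cluster(np.vstack([blob_a, blob_b]), epsilon=1.0, theta=3)
        assert cs.n_clusters == 2
        assert not np.any(cs.labels == NOISE)
        assert len(set(cs.labels[:20])) == 1 and len(set(cs.labels[20:])) == 1

    def test_isolated_point_is_noise(self):
        rng = np.random.default_rng(2)
        pts = np.vstack([rng.normal(0, 0.1, (30, 2)), [[50.0, 50.0]]])
        cs = cnn_cluster(pts, epsilon=1.0, theta=3)
        assert cs.labels[-1] == NOISE

    @pytest.mark.parametrize("require_direct", [True, False])
    def test_matches_brute_force_oracle(self, require_direct):
        """200 random instances of up to 100 points against the direct
        O(n^2) shared-neighbor + union-find oracle."""
        rng = np.random.default_rng(3)
        for trial in range(200):
            n = int(rng.integers(2, 101))
            d = int(rng.integers(1, 4))
            pts = rng.uniform(0, 4, (n, d))
            eps = float(rng.uniform(0.2, 2.0))
            theta = int(rng.integers(0, 6))
            ours = cnn_cluster(pts, epsilon=eps, theta=theta,
                               require_direct_neighbor=require_direct).labels
            ref = brute_force_cnn(pts, eps, theta,
                                  require_direct_neighbor=require_direct)
            assert same_partition(ours, ref), (
                f"trial {trial}: n={n} eps={eps:.3f} theta={theta}")

    def test_epsilon_monotonicity(self):
        """Raising epsilon at fixed theta never increases the number of
        clusters on nested instances."""
        rng = np.random.default_rng(4)
        pts = np.vstack([rng.normal(c, 0.3, (30, 2))
                         for c in ([0, 0], [3, 0], [0, 3], [3, 3])])
        counts = [cnn_cluster(pts, epsilon=e, theta=3).n_clusters
                  for e in (0.3, 0.6, 1.0, 2.0, 4.0, 8.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_empty_input(self):
        cs = cnn_cluster(np.empty((0, 2)), epsilon=1.0, theta=2)
        assert cs.n_clusters == 0 and len(cs.labels) == 0


def _toy_graph(intervals, edges, chis=None, weights=None):
    """Hand-build an MKMGraph for pathway tests."""
    chis = chis if chis is not None else np.linspace(0, 1, len(intervals))
    weights = weights if weights is not None else np.full(len(intervals),
                                                          1 / len(intervals))
    nodes = [MKMNode(node_id=i, interval=intervals[i],
                     members=np.array([i]), mean_chi=float(chis[i]),
                     mean_structure=np.zeros(2), weight=float(weights[i]))
             for i in range(len(intervals))]
    return MKMGraph(nodes=nodes, edges={tuple(sorted(e)): 1 for e in edges},
                    r_n=0.5, metric="euclidean",
                    n_intervals=max(intervals) + 1)


class TestBuildMkm:
    def test_overlapping_clouds_get_edge(self):
        rng = np.random.default_rng(5)
        cloud = rng.normal(0, 0.3, (40, 2))
        states = np.vstack([cloud, cloud + 0.01])
        chi = np.concatenate([np.full(40, 0.2), np.full(40, 0.6)])
        part = partition_by_chi(chi, 2)
        graph = build_mkm(states, chi, part, epsilon=1.0, theta=3, r_n=0.5)
        assert len(graph.nodes) == 2
        assert (0, 1) in graph.edges

    def test_distant_clouds_no_edge(self):
        rng = np.random.default_rng(6)
        states = np.vstack([rng.normal(0, 0.2, (40, 2)),
                            rng.normal(50, 0.2, (40, 2))])
        chi = np.concatenate([np.full(40, 0.2), np.full(40, 0.6)])
        part = partition_by_chi(chi, 2)
        graph = build_mkm(states, chi, part, epsilon=1.0, theta=3, r_n=0.5)
        assert graph.edges == {}

    def test_weights_normalized_and_members_disjoint(self, small_ensemble):
        from kinmap.isokann import IsokannConfig, NeuralRegressor, isokann_fit

        model, _ = isokann_fit(small_ensemble, NeuralRegressor(),
                               IsokannConfig(seed=0, max_iterations=30))
        chi = model.predict(small_ensemble.X0)
        part = partition_by_chi(chi, 3)
        graph = build_mkm(small_ensemble.X0, chi, part, epsilon=1.0,
                          theta=5, r_n=0.6)
        weights = np.array([n.weight for n in graph.nodes])
        assert weights.sum() == pytest.approx(1.0, abs=1e-12)
        all_members = np.concatenate([n.members for n in graph.nodes])
        assert len(all_members) == len(set(all_members))
        for node in graph.nodes:
            assert np.all(part.assignment[node.members] == node.interval)

    def test_all_noise_raises_empty_graph(self):
        states = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0], [10.0, 10.0]])
        chi = np.array([0.1, 0.4, 0.6, 0.9])
        part = partition_by_chi(chi, 2)
        with pytest.raises(EmptyGraphError):
            build_mkm(states, chi, part, epsilon=0.5, theta=3, r_n=0.5)

    def test_per_interval_parameters(self):
        rng = np.random.default_rng(7)
        states = np.vstack([rng.normal(0, 0.2, (30, 2)),
                            rng.normal(0, 0.2, (30, 2))])
        chi = np.concatenate([np.full(30, 0.2), np.full(30, 0.7)])
        part = partition_by_chi(chi, 2)
        graph = build_mkm(states, chi, part, epsilon=[1.0, 2.0],
                          theta=[3, 4], r_n=0.5)
        assert len(graph.nodes) == 2
        with pytest.raises(ValueError, match="per interval"):
            build_mkm(states, chi, part, epsilon=[1.0], theta=3, r_n=0.5)

    def test_json_roundtrip(self, tmp_path):
        graph = _toy_graph([0, 1, 1, 2],
                           [(0, 1), (0, 2), (1, 3), (2, 3)])
        path = tmp_path / "graph.json"
        graph.save_json(path)
        loaded = MKMGraph.load_json(path)
        assert loaded.edges == graph.edges
        assert [n.interval for n in loaded.nodes] == [0, 1, 1, 2]
        graph.save_graphml(tmp_path / "graph.graphml")
        assert (tmp_path / "graph.graphml").stat().st_size > 0


class TestEnumeratePathways:
    def test_linear_chain_single_path(self):
        graph = _toy_graph([0, 1, 2, 3], [(0, 1), (1, 2), (2, 3)])
        paths = enumerate_pathways(graph)
        assert len(paths) == 1
        assert paths[0].nodes == (0, 1, 2, 3)
        assert paths[0].length == 4

    def test_diamond_two_paths(self):
        graph = _toy_graph([0, 1, 1, 2], [(0, 1), (0, 2), (1, 3), (2, 3)],
                           chis=[0.0, 0.5, 0.5, 1.0])
        paths = enumerate_pathways(graph)
        assert sorted(p.nodes for p in paths) == [(0, 1, 3), (0, 2, 3)]

    def test_disconnected_returns_empty_with_warning(self):
        graph = _toy_graph([0, 1, 2], [(0, 1)])
        with pytest.warns(UserWarning, match="disconnected"):
            assert enumerate_pathways(graph) == []

    def test_truncation_flagged(self):
        # complete bipartite-ish ladder with many middle choices
        intervals = [0] + [1] * 6 + [2]
        edges = [(0, i) for i in range(1, 7)] + [(i, 7) for i in range(1, 7)]
        graph = _toy_graph(intervals, edges,
                           chis=[0.0] + [0.5] * 6 + [1.0])
        with pytest.warns(UserWarning, match="truncated"):
            paths = enumerate_pathways(graph, max_paths=3)
        assert len(paths) == 3

    def test_matches_exhaustive_enumeration_on_random_dags(self):
        """Random layered graphs of up to 12 nodes against networkx
        all_simple_paths on the interval-directed version."""
        rng = np.random.default_rng(8)
        for trial in range(100):
            n_nodes = int(rng.integers(4, 13))
            n_int = int(rng.integers(3, 6))
            intervals = sorted(int(rng.integers(0, n_int))
                               for _ in range(n_nodes))
            chis = [(i + rng.uniform(0.05, 0.95)) / n_int for i in intervals]
            edges = []
            for i in range(n_nodes):
                for j in range(i + 1, n_nodes):
                    if abs(intervals[i] - intervals[j]) == 1 \
                            and rng.random() < 0.5:
                        edges.append((i, j))
            graph = _toy_graph(intervals, edges, chis=chis)
            source = int(np.argmin(chis))
            sink = int(np.argmax(chis))
            expected = sorted(exhaustive_increasing_paths(
                n_nodes, intervals, edges, source, sink))
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                got = sorted(p.nodes for p in enumerate_pathways(graph))
            assert got == expected, f"trial {trial}"


class TestStructureExport:
    def test_molecular_nodes_written_as_xyz(self, tmp_path):
        rng = np.random.default_rng(12)
        graph = _toy_graph([0, 1], [(0, 1)])
        for node in graph.nodes:
            node.mean_structure = rng.normal(size=(4, 3))
        files = graph.export_structures(tmp_path)
        assert len(files) == 2
        text = files[0].read_text().splitlines()
        assert text[0] == "4"
        assert len(text) == 6

    def test_flat_structures_rejected(self, tmp_path):
        graph = _toy_graph([0, 1], [(0, 1)])
        with pytest.raises(ValueError, match="molecular"):
            graph.export_structures(tmp_path)
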