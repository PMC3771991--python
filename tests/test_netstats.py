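"""Directed centralities vs exhaustive oracles, hubs, cluster filtering."""

import itertools

import numpy as np
import pytest

from pcgc import (
    betweenness_centrality,
    cluster_extent_filter,
    clustering_coefficient,
    degree_centrality,
    identify_hubs,
    normalize_nodal,
    threshold_graph,
)


def brute_force_betweenness(adj):
    """Exhaustive all-pairs shortest-path enumeration (<= 8 nodes)."""
    n = adj.shape[0]
    # enumerate ALL simple paths per ordered pair, keep the shortest length
    # (weighted length = sum of 1/w), count paths through each node
    def all_paths(s, t):
        paths = []

        def extend(node, visited, length):
            if node == t:
                paths.append((length, tuple(visited)))
                return
            for nxt in range(n):
                if adj[node, nxt] > 0 and nxt not in visited:
                    extend(nxt, visited + [nxt], length + 1.0 / adj[node, nxt])

        extend(s, [s], 0.0)
        return paths

    bc = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            paths = all_paths(s, t)
            if not paths:
                continue
            best = min(length for length, _ in paths)
            shortest = [p for length, p in paths if np.isclose(length, best)]
            for p in shortest:
                for v in p[1:-1]:
                    bc[v] += 1.0 / len(shortest)
    return bc


class TestThresholdGraph:
    def test_strict_inequality_at_threshold(self):
        w = np.array([[0.0, 0.2], [0.3, 0.0]])
        w2 = np.array([[0.0, 0.31], [0.3, 0.0]])
        assert threshold_graph(w, 0.3).sum() == 0
        adj = threshold_graph(w2, 0.3)
        assert adj[0, 1] == 1.0 and adj[1, 0] == 0.0

    def test_weighted_mode_preserves_values(self):
        w = np.array([[0.0, 0.9], [0.5, 0.0]])
        adj = threshold_graph(w, 0.3, mode="weighted")
        assert adj[0, 1] == 0.9 and adj[1, 0] == 0.5

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            threshold_graph(np.array([[0.0, -0.1], [0.0, 0.0]]), 0.3)


class TestDegreeCentrality:
    def test_star_graph(self):
        adj = np.zeros((6, 6))
        adj[0, 1:] = 1.0
        assert degree_centrality(adj, "out")[0] == 5
        np.testing.assert_array_equal(degree_centrality(adj, "in")[1:], 1)

    def test_in_out_conservation(self, rng):
        adj = (rng.uniform(size=(7, 7)) > 0.6).astype(float)
        np.fill_diagonal(adj, 0.0)
        assert degree_centrality(adj, "in").sum() == degree_centrality(adj, "out").sum()

    def test_weighted_hand_example(self):
        adj = np.array([[0.0, 0.4, 0.0], [0.0, 0.0, 0.7], [0.2, 0.0, 0.0]])
        np.testing.assert_allclose(degree_centrality(adj, "out"), [0.4, 0.7, 0.2])
        np.testing.assert_allclose(degree_centrality(adj, "in"), [0.2, 0.4, 0.7])


class TestBetweenness:
    def test_directed_path_center(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = adj[1, 2] = 1.0
        np.testing.assert_allclose(betweenness_centrality(adj), [0, 1, 0])

    def test_complete_graph_all_zero(self):
        adj = np.ones((5, 5)) - np.eye(5)
        np.testing.assert_allclose(betweenness_centrality(adj), 0.0)

    @pytest.mark.parametrize("weighted", [False, True])
    def test_random_digraphs_match_enumeration_oracle(self, weighted):
        rng = np.random.default_rng(5)
        for _ in range(8):
            n = int(rng.integers(4, 8))
            adj = (rng.uniform(size=(n, n)) > 0.55).astype(float)
            if weighted:
                adj *= rng.uniform(0.2, 2.0, size=(n, n))
            np.fill_diagonal(adj, 0.0)
            got = betweenness_centrality(adj)
            expect = brute_force_betweenness(adj)
            np.testing.assert_allclose(got, expect, atol=1e-9)

    def test_permutation_equivariance(self, rng):
        adj = (rng.uniform(size=(6, 6)) > 0.5).astype(float)
        np.fill_diagonal(adj, 0.0)
        perm = rng.permutation(6)
        permuted = adj[np.ix_(perm, perm)]
        np.testing.assert_allclose(
            betweenness_centrality(permuted), betweenness_centrality(adj)[perm]
        )


class TestClusteringCoefficient:
    def test_full_mutual_clique_neighbourhood(self):
        adj = np.zeros((4, 4))
        adj[0, 1] = adj[0, 2] = adj[0, 3] = 1.0
        for i, j in itertools.permutations([1, 2, 3], 2):
            adj[i, j] = 1.0
        assert clustering_coefficient(adj, "out")[0] == 1.0

    def test_unconnected_neighbours(self):
        adj = np.zeros((4, 4))
        adj[0, 1] = adj[0, 2] = adj[0, 3] = 1.0
        assert clustering_coefficient(adj, "out")[0] == 0.0

    def test_hand_counted_five_node_digraph(self):
        adj = np.zeros((5, 5))
        edges = [(0, 1), (0, 2), (0, 3), (1, 2), (3, 1), (2, 4), (4, 0)]
        for i, j in edges:
            adj[i, j] = 1.0
        # node 0 out-neighbours {1,2,3}: directed links among them are
        # 1->2 and 3->1, so cc_out(0) = 2 / (3*2)
        assert clustering_coefficient(adj, "out")[0] == pytest.approx(2 / 6)
        # node 2 in-neighbours {0,1}: links among them: 0->1 only
        assert clustering_coefficient(adj, "in")[2] == pytest.approx(1 / 2)

    def test_low_degree_zero(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = 1.0
        np.testing.assert_array_equal(clustering_coefficient(adj, "out"), 0.0)


class TestNormalizeNodal:
    def test_single_subject_divides_by_mean(self):
        np.testing.assert_allclose(
            normalize_nodal(np.array([[2.0, 4.0, 6.0]])), [0.5, 1.0, 1.5]
        )

    def test_all_equal_gives_ones(self):
        np.testing.assert_allclose(normalize_nodal(np.full((3, 4), 7.0)), 1.0)

    def test_proportional_profiles_scale_invariant(self, rng):
        base = rng.uniform(1, 5, size=8)
        two = np.vstack([base, 3.0 * base])
        np.testing.assert_allclose(normalize_nodal(two), normalize_nodal(base[None, :]))

    def test_zero_mean_subject_rejected(self):
        with pytest.raises(ValueError, match="mean"):
            normalize_nodal(np.zeros((1, 4)))


class TestIdentifyHubs:
    def test_constructed_outlier_scores_three(self):
        base = np.ones(10)
        vecs = []
        for _ in range(3):
            v = base.copy()
            v[4] = 5.0
            vecs.append(v)
        score, hubs = identify_hubs(*vecs)
        assert score[4] == 3 and hubs[4]
        assert score.sum() == 3 and hubs.sum() == 1

    def test_single_criterion_not_a_hub(self):
        flat = np.linspace(0.9, 1.1, 10)
        spike = flat.copy()
        spike[7] = 9.0
        score, hubs = identify_hubs(spike, flat, flat)
        assert score[7] == 1 and not hubs[7]

    def test_constant_vectors_no_hubs(self):
        v = np.ones(6)
        score, hubs = identify_hubs(v, v, v)
        assert score.sum() == 0 and not hubs.any()

    def test_hand_computed_mean_sd_criterion(self):
        v = np.array([1.0, 1, 1, 1, 1, 1, 1, 1, 1, 4])
        # mean = 1.3, sd(ddof=1) ~ 0.9487: only node 9 exceeds 2.2487
        score, _ = identify_hubs(v, np.ones(10), np.ones(10))
        expect = (v > v.mean() + v.std(ddof=1)).astype(int)
        np.testing.assert_array_equal(score, expect)


class TestClusterExtentFilter:
    def test_isolated_voxel_removed(self):
        grid = np.zeros((8, 8, 8), dtype=bool)
        grid[4, 4, 4] = True
        assert not cluster_extent_filter(grid, 27).any()

    def test_exact_27_block_kept(self):
        grid = np.zeros((8, 8, 8), dtype=bool)
        grid[1:4, 1:4, 1:4] = True
        out = cluster_extent_filter(grid, 27)
        np.testing.assert_array_equal(out, grid)

    def test_size_26_vs_28_components(self):
        from scipy import ndimage

        grid = np.zeros((12, 12, 12), dtype=bool)
        block_a = np.zeros((3, 3, 3), dtype=bool)
        block_a[:] = True
        block_a[0, 0, 0] = False  # 26 voxels
        grid[1:4, 1:4, 1:4] = block_a
        grid[7:10, 7:10, 7:10] = True
        grid[7, 7, 9] = False
        grid[9, 9, 10] = True
        grid[8, 9, 10] = True  # second component: 27 - 1 + 2 = 28 voxels
        out = cluster_extent_filter(grid, 27)
        labeled, n = ndimage.label(out, structure=np.ones((3, 3, 3)))
        assert n == 1
        assert out.sum() == 28
        assert not out[1:4, 1:4, 1:4].any()
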