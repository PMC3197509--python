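"""Clustering algorithms against planted truth and exhaustive oracles."""

import itertools
import math

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import pymedusa as pm
from pymedusa.clustering import (
    APParams,
    ap_cluster,
    kmeans_features,
    net_similarity,
    similarity_matrix,
)
from pymedusa.colors import CLUSTER_PALETTE
from pymedusa.fixtures import FixtureSpec, generate

from conftest import mknet


def ari(net, clustering, truth):
    names = net.node_names
    return adjusted_rand_score([truth[n] for n in names], [clustering.assignment[n] for n in names])


class TestKMeans:
    def test_k_equals_n_gives_singletons_with_zero_objective(self):
        fx = generate(FixtureSpec(kind="random_graph", n=8, params={"p": 0.4}, seed=0))
        cl = pm.cluster_kmeans(fx.network, 8, seed=0)
        assert cl.k == 8
        assert sorted(cl.assignment.values()) == list(range(8))
        assert cl.meta["objective"] == pytest.approx(0.0, abs=1e-12)

    def test_k_one_objective_is_total_variance(self):
        fx = generate(FixtureSpec(kind="random_graph", n=10, params={"p": 0.3}, seed=1))
        cl = pm.cluster_kmeans(fx.network, 1, seed=0)
        from pymedusa.layouts import _adjacency

        X = _adjacency(fx.network)
        expected = float(((X - X.mean(axis=0)) ** 2).sum())
        assert cl.meta["objective"] == pytest.approx(expected)

    def test_separated_clouds_recovered_exactly(self):
        fx = generate(
            FixtureSpec(kind="gaussian_clouds", n=40, params={"k": 2, "separation": 10.0}, seed=1)
        )
        cl = pm.cluster_kmeans(fx.network, 2, seed=1, feature_source="coordinates", layout=fx.coords)
        assert ari(fx.network, cl, fx.labels) == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_objective_monotone_nonincreasing(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0, 1, (30, 3))
        _, _, history = kmeans_features(X, 4, seed=seed)
        assert all(b <= a + 1e-9 for a, b in zip(history, history[1:]))

    def test_k_out_of_range_rejected(self, triangle):
        with pytest.raises(ValueError):
            pm.cluster_kmeans(triangle, 4)
        with pytest.raises(ValueError):
            pm.cluster_kmeans(triangle, 0)

    def test_coordinates_source_requires_layout(self, triangle):
        with pytest.raises(ValueError):
            pm.cluster_kmeans(triangle, 2, feature_source="coordinates")

    def test_deterministic_given_seed(self):
        fx = generate(FixtureSpec(kind="planted_partition", n=20, params={"k": 2, "block_size": 10}, seed=3))
        a = pm.cluster_kmeans(fx.network, 2, seed=5).assignment
        assert a == pm.cluster_kmeans(fx.network, 2, seed=5).assignment


class TestSpectral:
    def test_two_disconnected_triangles_split_on_components(self, two_triangles):
        cl = pm.cluster_spectral(two_triangles, 2, seed=0)
        groups = {cl.assignment[n] for n in ["a1", "a2", "a3"]}
        assert len(groups) == 1
        assert cl.assignment["b1"] not in groups

    def test_planted_partition_recovered(self):
        fx = generate(
            FixtureSpec(
                kind="planted_partition",
                params={"k": 2, "block_size": 15, "p_in": 0.9, "p_out": 0.02},
                seed=2,
            )
        )
        cl = pm.cluster_spectral(fx.network, 2, seed=0)
        assert ari(fx.network, cl, fx.labels) >= 0.95

    def test_complete_graph_both_clusters_nonempty(self):
        net = mknet("ABCDE")
        for a, b in itertools.combinations("ABCDE", 2):
            net.add_edge(pm.Edge(source=a, target=b))
        cl = pm.cluster_spectral(net, 2, seed=0)
        assert set(cl.assignment.values()) == {0, 1}

    @pytest.mark.parametrize("seed", range(10))
    def test_component_count_clusters_recover_components_exactly(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 5))
        net = pm.Network()
        truth = {}
        for block in range(k):
            size = int(rng.integers(3, 7))
            names = [f"c{block}n{i}" for i in range(size)]
            for name in names:
                net.add_node(pm.Node(name=name))
                truth[name] = block
            for a, b in itertools.combinations(names, 2):
                if rng.uniform() < 0.7:
                    net.add_edge(pm.Edge(source=a, target=b))
            # keep each block connected
            for a, b in zip(names, names[1:]):
                if not net.edges_between(a, b):
                    net.add_edge(pm.Edge(source=a, target=b))
        cl = pm.cluster_spectral(net, k, seed=seed)
        assert ari(net, cl, truth) == 1.0

    def test_k_bounds(self, triangle):
        with pytest.raises(ValueError):
            pm.cluster_spectral(triangle, 1)


class TestAffinityPropagation:
    def test_single_node_is_its_own_exemplar(self):
        net = mknet("A")
        cl = pm.cluster_affinity_propagation(net)
        assert cl.k == 1 and cl.exemplars == {0: "A"}

    def test_two_separated_dyads_give_two_clusters(self):
        net = mknet("ABCD", [("A", "B", 1, 0.9), ("C", "D", 1, 0.9)])
        cl = pm.cluster_affinity_propagation(net)
        assert cl.k == 2
        assert cl.assignment["A"] == cl.assignment["B"]
        assert cl.assignment["C"] == cl.assignment["D"]
        assert cl.assignment["A"] != cl.assignment["C"]

    def test_exemplars_belong_to_their_own_cluster(self):
        fx = generate(FixtureSpec(kind="planted_partition", params={"k": 2, "block_size": 6}, seed=1))
        cl = pm.cluster_affinity_propagation(fx.network)
        for cid, exemplar in cl.exemplars.items():
            assert cl.assignment[exemplar] == cid

    @pytest.mark.parametrize("seed", range(10))
    def test_net_similarity_near_exhaustive_optimum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        M = rng.uniform(0, 1, (n, n))
        S = (M + M.T) / 2
        np.fill_diagonal(S, 0.0)
        pref = float(np.median(S[~np.eye(n, dtype=bool)]))
        exemplars, _, _ = ap_cluster(S.copy(), APParams(preference=pref))
        achieved = net_similarity(S, exemplars, pref)
        best = max(
            net_similarity(S, np.array(combo), pref)
            for r in range(1, n + 1)
            for combo in itertools.combinations(range(n), r)
        )
        assert achieved >= best - 0.05 * abs(best)

    def test_similarity_matrix_floors_non_edges(self):
        net = mknet("ABC", [("A", "B", 1, 0.7)])
        _, S = similarity_matrix(net)
        assert S[0, 1] == 0.7 and S[0, 2] == -1.0

    def test_damping_bounds_enforced(self):
        with pytest.raises(ValueError):
            APParams(damping=0.4)


class TestPredefinedClusters:
    def test_single_label_covering_all_nodes(self, tmp_path, triangle):
        path = tmp_path / "clusters.tsv"
        path.write_text("A\tx\nB\tx\nC\tx\n")
        cl = pm.read_predefined_clusters(triangle, path)
        assert cl.k == 1 and set(cl.assignment.values()) == {0}

    def test_first_appearance_order_assigns_ids(self, tmp_path, triangle):
        path = tmp_path / "clusters.tsv"
        path.write_text("A\tx\nB\ty\nC\tx\n")
        cl = pm.read_predefined_clusters(triangle, path)
        assert cl.assignment == {"A": 0, "C": 0, "B": 1}

    def test_empty_file_gives_single_unclustered_cluster(self, tmp_path, triangle):
        path = tmp_path / "clusters.tsv"
        path.write_text("")
        cl = pm.read_predefined_clusters(triangle, path)
        assert cl.k == 1 and set(cl.assignment.values()) == {0}

    def test_unknown_node_row_warned_and_skipped(self, tmp_path, triangle):
        path = tmp_path / "clusters.tsv"
        path.write_text("A\tx\nZZZ\tx\n")
        with pytest.warns(UserWarning, match="ZZZ"):
            cl = pm.read_predefined_clusters(triangle, path)
        assert "ZZZ" not in cl.assignment

    def test_malformed_line_reports_line_number(self, tmp_path, triangle):
        path = tmp_path / "clusters.tsv"
        path.write_text("A\tx\nnot a valid line\n")
        with pytest.raises(pm.ParseError) as err:
            pm.read_predefined_clusters(triangle, path)
        assert err.value.line == 2

    def test_export_import_roundtrip(self, tmp_path, two_triangles):
        cl = pm.cluster_spectral(two_triangles, 2, seed=0)
        path = tmp_path / "out.tsv"
        pm.export_clusters(cl, path)
        assert path.read_text().count("\n") == two_triangles.n_nodes
        back = pm.read_predefined_clusters(two_triangles, path)
        assert back.assignment == cl.assignment


class TestCircleLayoutAndColors:
    def test_members_equidistant_from_cluster_center(self, two_triangles):
        cl = pm.cluster_spectral(two_triangles, 2, seed=0)
        layout = pm.cluster_circle_layout(two_triangles, cl)
        for cid in range(cl.k):
            members = cl.members(cid)
            pts = np.array([layout.coords[m] for m in members])
            center = pts.mean(axis=0)
            radii = np.linalg.norm(pts - center, axis=1)
            assert radii.max() - radii.min() < 1e-9

    def test_two_cluster_centers_symmetric_about_canvas_center(self, two_triangles):
        cl = pm.cluster_spectral(two_triangles, 2, seed=0)
        layout = pm.cluster_circle_layout(two_triangles, cl)
        centers = [
            np.array([layout.coords[m] for m in cl.members(cid)]).mean(axis=0)
            for cid in range(2)
        ]
        assert np.allclose(centers[0] + centers[1], [1.0, 1.0], atol=1e-9)

    def test_three_clusters_of_four_distinct_centers(self):
        net = mknet([f"n{i}" for i in range(12)])
        assignment = {f"n{i}": i % 3 for i in range(12)}
        from pymedusa.clustering import _finish

        cl = _finish(assignment, "predefined")
        layout = pm.cluster_circle_layout(net, cl)
        assert len(layout.coords) == 12
        centers = {
            tuple(np.round(np.array([layout.coords[m] for m in cl.members(cid)]).mean(axis=0), 6))
            for cid in range(3)
        }
        assert len(centers) == 3

    def test_distinct_clusters_get_distinct_palette_colors(self):
        from pymedusa.clustering import _finish

        cl = _finish({f"n{i}": i for i in range(12)}, "predefined")
        assert len(set(cl.colors.values())) == 12
        assert set(cl.colors.values()) <= set(CLUSTER_PALETTE)

    def test_kmeans_singletons_on_distinct_features(self):
        fx = generate(FixtureSpec(kind="gaussian_clouds", n=6, params={"k": 3}, seed=2))
        cl = pm.cluster_kmeans(fx.network, 6, seed=0, feature_source="coordinates", layout=fx.coords)
        assert cl.k == 6
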