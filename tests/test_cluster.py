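"""Neighborhood graph, Leiden clustering, subclustering, consolidation."""

import igraph as ig
import leidenalg
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from flowpheno.annotate import AnnotationMap
from flowpheno.cluster import (ClusterAssignment, build_knn_graph, consolidate,
                               induced_subgraph, leiden_cluster, subcluster,
                               umap_embed)
from flowpheno.exceptions import ConfigError, FlowPhenoError


def brute_force_knn(matrix, k):
    d = np.linalg.norm(matrix[:, None, :] - matrix[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    return np.argsort(d, axis=1, kind="stable")[:, :k]


class TestKnnGraph:
    def test_three_collinear_points_k1(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        g = build_knn_graph(pts, k=1)
        assert g.neighbors[0, 0] == 1   # left endpoint -> middle
        assert g.neighbors[2, 0] == 1   # right endpoint -> middle
        assert g.neighbors[1, 0] == 0   # middle -> nearer endpoint

    def test_exactness_against_brute_force(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(500, 5))
        g = build_knn_graph(pts, k=15)
        oracle = brute_force_knn(pts, 15)
        # compare as sets per row (equidistant ties may permute)
        for i in range(500):
            assert set(g.neighbors[i]) == set(oracle[i])

    def test_full_jaccard_weight_for_mutual_duplicates(self):
        # two coincident events that are mutual nearest neighbors and share
        # all their other neighbors have SNN weight exactly 1
        pts = np.array([[0.0, 0.0], [0.0, 0.0],
                        [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        g = build_knn_graph(pts, k=3)
        edge = np.flatnonzero((g.edges[:, 0] == 0) & (g.edges[:, 1] == 1))
        assert len(edge) == 1
        assert g.weights[edge[0]] == pytest.approx(1.0)

    def test_k_truncated_with_warning(self):
        pts = np.random.default_rng(0).normal(size=(5, 2))
        with pytest.warns(UserWarning, match="truncating"):
            g = build_knn_graph(pts, k=10)
        assert g.k == 4

    def test_no_self_edges_and_weights_nonnegative(self):
        pts = np.random.default_rng(1).normal(size=(80, 3))
        g = build_knn_graph(pts, k=8)
        assert np.all(g.edges[:, 0] != g.edges[:, 1])
        assert np.all(g.weights >= 0)
        assert np.all((g.neighbors != np.arange(80)[:, None]))


class TestLeiden:
    def test_three_gaussians_recovered(self, fixture_library, display_events):
        ev = display_events("three_gaussians")
        truth = fixture_library["three_gaussians"].truth.population
        g = build_knn_graph(ev.intensities, k=20)
        assignment = leiden_cluster(g, resolution=0.3, seed=0)
        assert len(assignment.leaf_labels) == 3
        assert adjusted_rand_score(truth, assignment.labels) >= 0.99

    def test_single_gaussian_low_resolution_one_cluster(self):
        pts = np.random.default_rng(3).normal(0, 1, size=(800, 4))
        g = build_knn_graph(pts, k=20)
        assignment = leiden_cluster(g, resolution=0.1, seed=0)
        assert len(assignment.leaf_labels) == 1

    def test_deterministic_given_seed(self, display_events):
        ev = display_events("three_gaussians")
        g = build_knn_graph(ev.intensities, k=20)
        a = leiden_cluster(g, resolution=0.5, seed=42)
        b = leiden_cluster(g, resolution=0.5, seed=42)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_labels_ordered_by_size(self, display_events):
        ev = display_events("three_gaussians")
        g = build_knn_graph(ev.intensities, k=20)
        assignment = leiden_cluster(g, resolution=0.3, seed=0)
        sizes = [np.sum(assignment.labels == l)
                 for l in sorted(assignment.leaf_labels, key=int)]
        assert sizes == sorted(sizes, reverse=True)

    def test_permutation_equivariance(self, fixture_library, display_events):
        ev = display_events("three_gaussians")
        perm = np.random.default_rng(4).permutation(ev.n_events)
        a = leiden_cluster(build_knn_graph(ev.intensities, k=20), 0.3, 0)
        b = leiden_cluster(build_knn_graph(ev.intensities[perm], k=20), 0.3, 0)
        assert adjusted_rand_score(a.labels[perm], b.labels) == pytest.approx(1.0)


class TestSubcluster:
    def test_equivalent_to_fresh_leiden_on_induced_subgraph(
            self, display_events):
        ev = display_events("nested_subsets")
        idx = np.arange(1000)
        g = build_knn_graph(ev.intensities[idx], k=15)
        assignment = leiden_cluster(g, resolution=0.3, seed=0)
        target = assignment.leaf_labels[0]
        result = subcluster(g, assignment, target, resolution=0.8, seed=7)

        # oracle: run leidenalg directly on the independently rebuilt
        # induced subgraph with the same renormalized weights
        members = assignment.members(target)
        sub_edges, sub_weights = induced_subgraph(g, members)
        graph = ig.Graph(n=len(members), edges=[tuple(e) for e in sub_edges])
        part = leidenalg.find_partition(
            graph, leidenalg.RBConfigurationVertexPartition,
            weights=list(sub_weights), resolution_parameter=0.8, seed=7,
            n_iterations=2)
        child = np.array([result.labels[i] for i in members])
        assert adjusted_rand_score(part.membership, child) == pytest.approx(1.0)
        # the rest of the partition is untouched
        others = np.setdiff1d(np.arange(len(idx)), members)
        np.testing.assert_array_equal(assignment.labels[others],
                                      result.labels[others])

    def test_two_component_cluster_splits(self, fixture_library,
                                          display_events):
        # a parent cluster generated as a 2-component mixture (CD62L-high
        # and -low CD4 T cells assigned one parent label) splits cleanly
        ev = display_events("nested_subsets")
        truth = fixture_library["nested_subsets"].truth.population
        g = build_knn_graph(ev.intensities, k=20)
        labels = np.where(
            np.isin(truth, ["CD4_T_CD62Lhi", "CD4_T_CD62Llo"]), "1",
            np.where(truth == "CD8_T", "2", "3")).astype(object)
        assignment = ClusterAssignment(labels=labels)
        result = subcluster(g, assignment, "1", resolution=0.3, seed=0)
        members = assignment.members("1")
        children = set(result.labels[members])
        assert len(children) == 2
        assert adjusted_rand_score(truth[members],
                                   result.labels[members]) >= 0.95
        # hierarchy integrity: children nest inside the parent
        for c in children:
            assert c.startswith("1.")

    def test_homogeneous_target_yields_single_child(self):
        pts = np.random.default_rng(5).normal(0, 1, size=(600, 3))
        g = build_knn_graph(pts, k=15)
        assignment = leiden_cluster(g, resolution=0.1, seed=0)
        target = assignment.leaf_labels[0]
        result = subcluster(g, assignment, target, resolution=0.05, seed=0)
        members = assignment.members(target)
        assert set(result.labels[members]) == {f"{target}.1"}

    def test_unknown_label_errors(self, display_events):
        ev = display_events("three_gaussians")
        g = build_knn_graph(ev.intensities[:500], k=10)
        assignment = leiden_cluster(g, 0.3, 0)
        with pytest.raises(FlowPhenoError):
            subcluster(g, assignment, "99", 1.0, 0)

    def test_hierarchy_partitions_events(self, display_events):
        ev = display_events("nested_subsets")
        g = build_knn_graph(ev.intensities[:1500], k=15)
        assignment = leiden_cluster(g, resolution=0.3, seed=0)
        for target in list(assignment.leaf_labels):
            assignment = subcluster(g, assignment, target, 0.5, 0)
        # leaf sets partition all events; every child nests in its parent
        assert len(assignment.labels) == 1500
        for label in assignment.leaf_labels:
            parent = label.rsplit(".", 1)[0]
            members = set(assignment.members(label))
            assert members <= set(assignment.members(parent))


class TestConsolidate:
    def _assignment(self):
        labels = np.array(["1"] * 4 + ["2"] * 3 + ["3"] * 3, dtype=object)
        return ClusterAssignment(labels=labels)

    def test_equivalent_annotations_merged(self):
        assignment = self._assignment()
        annotation = AnnotationMap(mapping={"1": "Classical monocyte",
                                           "2": "Classical monocyte",
                                           "3": "B cell"})
        merged = consolidate(assignment, annotation)
        assert len(merged.leaf_labels) == 2
        merged_label = merged.labels[0]
        assert (merged.labels[:7] == merged_label).all()

    def test_all_distinct_is_identity(self):
        assignment = self._assignment()
        annotation = AnnotationMap(mapping={"1": "a", "2": "b", "3": "c"})
        merged = consolidate(assignment, annotation)
        np.testing.assert_array_equal(merged.labels, assignment.labels)

    def test_merged_counts_are_additive(self):
        assignment = self._assignment()
        annotation = AnnotationMap(mapping={"1": "x", "2": "x", "3": "y"})
        merged = consolidate(assignment, annotation)
        label = merged.labels[0]
        assert np.sum(merged.labels == label) == 4 + 3

    def test_unannotated_leaf_errors(self):
        assignment = self._assignment()
        with pytest.raises(FlowPhenoError, match="3"):
            consolidate(assignment, AnnotationMap(mapping={"1": "a", "2": "b"}))


class TestUmap:
    @pytest.fixture(scope="class")
    def embedding_setup(self, fixture_library, display_events):
        ev = display_events("three_gaussians")
        idx = np.arange(0, ev.n_events, 3)  # thin for speed
        matrix = ev.intensities[idx]
        truth = fixture_library["three_gaussians"].truth.population[idx]
        return matrix, truth, umap_embed(matrix, seed=0)

    def test_shape_and_determinism(self, embedding_setup):
        matrix, _, coords = embedding_setup
        assert coords.shape == (matrix.shape[0], 2)
        np.testing.assert_array_equal(coords, umap_embed(matrix, seed=0))

    def test_population_separation_in_embedding(self, embedding_setup):
        _, truth, coords = embedding_setup
        assert silhouette_score(coords, truth) > 0.3

    def test_trustworthiness(self, embedding_setup):
        from sklearn.manifold import trustworthiness
        matrix, _, coords = embedding_setup
        assert trustworthiness(matrix, coords, n_neighbors=15) >= 0.80

    def test_minimum_size(self):
        with pytest.raises(ConfigError):
            umap_embed(np.zeros((5, 2)), seed=0)
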