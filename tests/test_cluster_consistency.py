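import numpy as np
import pytest
from scipy.spatial.distance import cdist
from sklearn.metrics import silhouette_samples

from swblab.exceptions import DimensionError, ParameterError, ValidationError
from swblab.cluster_consistency import (
    adjusted_rand,
    consistency_table,
    cluster_distance_matrix,
    isomap_embed,
    kmeans_partition,
    silhouette,
)


def _line_distances(positions):
    positions = np.asarray(positions, dtype=float)
    return np.abs(positions[:, None] - positions[None, :])


class TestIsomap:
    def test_path_graph_geodesics_recovered(self):
        D = _line_distances([0, 1, 2, 3])
        emb = isomap_embed(D, n_neighbors=1)
        geo = cdist(emb.coords, emb.coords)
        np.testing.assert_allclose(geo, D, atol=1e-6)

    def test_euclidean_configuration_reproduced_exactly(self, rng):
        pts = rng.normal(size=(6, 2))
        D = cdist(pts, pts)
        emb = isomap_embed(D, n_neighbors=5)  # fully connected graph
        np.testing.assert_allclose(cdist(emb.coords, emb.coords), D, atol=1e-6)

    def test_disconnected_graph_repaired(self):
        # two tight pairs far apart: the 1-NN graph has two components
        D = _line_distances([0.0, 0.1, 10.0, 10.1])
        emb = isomap_embed(D, n_neighbors=1)
        assert emb.connectivity_repair
        assert np.all(np.isfinite(emb.coords))

    def test_matches_sklearn_on_connected_graph(self, rng):
        from sklearn.manifold import Isomap

        pts = rng.normal(size=(8, 3))
        D = cdist(pts, pts)
        emb = isomap_embed(D, n_neighbors=7)
        ref = Isomap(n_neighbors=7, n_components=2, metric="precomputed").fit_transform(D)
        np.testing.assert_allclose(
            cdist(emb.coords, emb.coords), cdist(ref, ref), atol=1e-6
        )

    def test_asymmetric_input_rejected(self):
        D = np.array([[0, 1, 2, 3], [1, 0, 1, 2], [2, 1, 0, 1], [3.5, 2, 1, 0.0]])
        with pytest.raises(ValidationError):
            isomap_embed(D)


class TestKmeans:
    def test_separated_clouds_recovered(self, rng):
        pts = np.vstack([rng.normal(0, 0.1, (5, 2)), rng.normal(10, 0.1, (5, 2))])
        labels = kmeans_partition(pts, 2, restarts=10, seed=0)
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_k_equals_n_isolates_every_point(self, rng):
        pts = rng.normal(size=(6, 2))
        labels = kmeans_partition(pts, 6, restarts=5, seed=0)
        assert len(set(labels)) == 6

    def test_seeded_determinism_and_k_bound(self, rng):
        pts = rng.normal(size=(10, 2))
        a = kmeans_partition(pts, 3, seed=42)
        b = kmeans_partition(pts, 3, seed=42)
        np.testing.assert_array_equal(a, b)
        with pytest.raises(ParameterError):
            kmeans_partition(pts, 11)


class TestSilhouette:
    def test_hand_case(self):
        # by direct evaluation: outer points a = 1, b = 10.5; inner a = 1, b = 9.5
        pts = np.array([[0.0], [1.0], [10.0], [11.0]])
        mean_s, per = silhouette(pts, np.array([0, 0, 1, 1]))
        np.testing.assert_allclose(per, [9.5 / 10.5, 8.5 / 9.5, 8.5 / 9.5, 9.5 / 10.5])
        assert mean_s == pytest.approx((9.5 / 10.5 + 8.5 / 9.5) / 2, abs=1e-12)

    def test_equal_cohesion_and_separation_scores_zero(self):
        D = np.ones((4, 4)) - np.eye(4)
        mean_s, _ = silhouette(D, np.array([0, 0, 1, 1]), precomputed=True)
        assert mean_s == pytest.approx(0.0, abs=1e-12)

    def test_perfectly_tight_clusters_score_one(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [5.0, 5.0]])
        mean_s, _ = silhouette(pts, np.array([0, 0, 1, 1]))
        assert mean_s == pytest.approx(1.0)

    def test_singleton_cluster_scores_zero(self):
        pts = np.array([[0.0], [1.0], [5.0]])
        _, per = silhouette(pts, np.array([0, 0, 1]))
        assert per[2] == 0.0

    def test_matches_explicit_loop_oracle_and_sklearn(self, rng):
        pts = rng.normal(size=(30, 2))
        labels = rng.integers(0, 3, size=30)
        mean_s, per = silhouette(pts, labels)
        D = cdist(pts, pts)
        for i in range(30):  # brute-force oracle, explicit per-pair loops
            same = [j for j in range(30) if labels[j] == labels[i] and j != i]
            a = sum(D[i, j] for j in same) / len(same)
            b = min(
                sum(D[i, j] for j in range(30) if labels[j] == c)
                / sum(labels[j] == c for j in range(30))
                for c in set(labels) - {labels[i]}
            )
            assert per[i] == pytest.approx((b - a) / max(a, b), abs=1e-12)
        np.testing.assert_allclose(per, silhouette_samples(pts, labels), atol=1e-10)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValidationError):
            silhouette(np.zeros((4, 2)), np.zeros(4, dtype=int))


class TestAdjustedRand:
    def test_identical_partitions_score_one(self):
        assert adjusted_rand([0, 0, 1, 1, 2], [0, 0, 1, 1, 2]) == 1.0

    def test_crossed_partition_hand_case(self):
        assert adjusted_rand([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(-0.5)

    def test_singletons_vs_one_cluster_is_chance(self):
        assert adjusted_rand(np.arange(6), np.zeros(6)) == pytest.approx(0.0)

    def test_symmetry_and_label_renaming(self, rng):
        a = rng.integers(0, 3, size=30)
        b = rng.integers(0, 4, size=30)
        assert adjusted_rand(a, b) == pytest.approx(adjusted_rand(b, a), abs=1e-12)
        renamed = np.array([2, 0, 1])[a]
        assert adjusted_rand(a, b) == pytest.approx(adjusted_rand(renamed, b), abs=1e-12)

    def test_random_partitions_center_on_zero(self, rng):
        # chance calibration: 1000 independent partitions of 27 items, k = 3
        vals = [
            adjusted_rand(rng.integers(0, 3, 27), rng.integers(0, 3, 27))
            for _ in range(1000)
        ]
        assert abs(np.mean(vals)) < 0.02

    def test_length_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            adjusted_rand([0, 1], [0, 1, 2])


class TestConsistencyTable:
    def test_identical_methods_agree_everywhere(self, rng):
        pts = np.vstack([rng.normal(0, 0.2, (6, 2)), rng.normal(8, 0.2, (6, 2))])
        D = cdist(pts, pts)
        _, parts = cluster_distance_matrix(D, ks=(2, 3), n_neighbors=3, seed=1)
        table = consistency_table({"m1": parts, "m2": parts}, ks=(2, 3))
        assert np.allclose(table["ari"], 1.0)

    def test_id_mismatch_rejected(self, rng):
        pts = rng.normal(size=(6, 2))
        D = cdist(pts, pts)
        _, p1 = cluster_distance_matrix(D, ids=[f"a{i}" for i in range(6)], ks=(2,), n_neighbors=3)
        _, p2 = cluster_distance_matrix(D, ids=[f"b{i}" for i in range(6)], ks=(2,), n_neighbors=3)
        with pytest.raises(ValidationError):
            consistency_table({"m1": p1, "m2": p2}, ks=(2,))
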