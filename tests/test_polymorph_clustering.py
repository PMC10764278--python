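import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from filapoly import (
    ClusteringConfig,
    GeneratorConfig,
    assignment_from_labels,
    cluster_homogeneity,
    cosine_distance,
    distance_matrix,
    flatten_dendrogram,
    generate_polymorph_dataset,
    iterate_polymorph_clustering,
    make_reclassifier,
    merge_small_clusters,
    profiles_from_records,
    upgma_linkage,
)


def brute_force_average_linkage(D):
    """Independent O(n^3) oracle: clusters as leaf sets, distance = mean
    over all leaf pairs of the original matrix."""
    n = D.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    heights = []
    merged = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        new = clusters[a] | clusters[b]
        merged.append((clusters[a], clusters[b], d))
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(new)
    return heights, merged


def cophenetic_from_dendrogram(dend):
    n = dend.n_leaves
    C = np.zeros((n, n))
    for k, (a, b, h, _) in enumerate(dend.merges):
        for i in dend.leaves_under(a):
            for j in dend.leaves_under(b):
                C[i, j] = C[j, i] = h
    return C


def cophenetic_from_oracle(merged, n):
    C = np.zeros((n, n))
    for A, B, h in merged:
        for i in A:
            for j in B:
                C[i, j] = C[j, i] = h
    return C


def random_distance_matrix(rng, n):
    M = rng.uniform(0.01, 1.0, size=(n, n))
    D = (M + M.T) / 2
    np.fill_diagonal(D, 0.0)
    return D


class TestCosineDistance:
    def test_identity_is_zero(self):
        u = np.array([0.2, 0.5, 0.3])
        assert cosine_distance(u, u) == 0.0

    def test_disjoint_one_hot_is_one(self):
        assert cosine_distance([1, 0, 0], [0, 0, 1]) == 1.0

    def test_half_overlap(self):
        assert cosine_distance([1, 1, 0], [1, 0, 1]) == pytest.approx(0.5)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_distance([0, 0], [1, 0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 10), min_size=2, max_size=8),
        st.floats(0.01, 100.0),
    )
    def test_scale_invariance(self, vals, scale):
        """Raw counts and normalised distributions give the same distance."""
        u = np.asarray(vals) + 0.01
        v = u[::-1].copy()
        assert cosine_distance(u * scale, v) == pytest.approx(
            cosine_distance(u, v), abs=1e-12
        )


class TestDistanceMatrix:
    def test_matches_pairwise_calls(self, profile_factory):
        rng = np.random.default_rng(0)
        profiles = [
            profile_factory(("m", i), 10, rng.uniform(0.01, 1, 6))
            for i in range(8)
        ]
        D = distance_matrix(profiles)
        for i in range(8):
            for j in range(8):
                expected = (
                    0.0 if i == j else cosine_distance(
                        profiles[i].distribution, profiles[j].distribution
                    )
                )
                assert D[i, j] == pytest.approx(expected, abs=1e-12)

    def test_identical_and_orthogonal(self, profile_factory):
        same = [profile_factory(("m", i), 5, [1, 1, 0]) for i in range(2)]
        assert distance_matrix(same)[0, 1] == pytest.approx(0.0, abs=1e-12)
        hots = [profile_factory(("m", i), 5, np.eye(3)[i]) for i in range(3)]
        D = distance_matrix(hots)
        assert np.allclose(D[np.triu_indices(3, 1)], 1.0)

    def test_requires_two_profiles(self, profile_factory):
        with pytest.raises(ValueError):
            distance_matrix([profile_factory(("m", 1), 5, [1, 2])])


class TestUpgma:
    def test_two_leaves(self):
        D = np.array([[0.0, 0.4], [0.4, 0.0]])
        dend = upgma_linkage(D)
        assert dend.merges == ((0, 1, 0.4, 2),)

    def test_three_leaf_hand_example(self):
        D = np.array([[0, 0.2, 0.6], [0.2, 0, 0.8], [0.6, 0.8, 0]])
        dend = upgma_linkage(D)
        (a0, b0, h0, s0), (a1, b1, h1, s1) = dend.merges
        assert (a0, b0, h0, s0) == (0, 1, 0.2, 2)
        assert (a1, b1, s1) == (2, 3, 3)
        assert h1 == pytest.approx(0.7)  # (0.6 + 0.8) / 2

    def test_validation(self):
        with pytest.raises(ValueError):
            upgma_linkage(np.array([[0, -1.0], [-1.0, 0]]))
        with pytest.raises(ValueError):
            upgma_linkage(np.array([[0, 1.0], [0.5, 0]]))

    @pytest.mark.parametrize("n", [3, 5, 8, 12])
    def test_agrees_with_brute_force_oracle(self, n):
        rng = np.random.default_rng(n)
        for _ in range(10):
            D = random_distance_matrix(rng, n)
            dend = upgma_linkage(D)
            heights, merged = brute_force_average_linkage(D)
            ours = [m[2] for m in dend.merges]
            np.testing.assert_allclose(ours, heights, atol=1e-12)
            np.testing.assert_allclose(
                cophenetic_from_dendrogram(dend),
                cophenetic_from_oracle(merged, n),
                atol=1e-12,
            )

    def test_agrees_with_scipy_average_linkage(self):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(7)
        for n in (4, 9, 12):
            D = random_distance_matrix(rng, n)
            Z = linkage(squareform(D, checks=False), method="average")
            ours = upgma_linkage(D).to_linkage()
            np.testing.assert_allclose(ours[:, 2], Z[:, 2], atol=1e-12)

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            D = random_distance_matrix(rng, 10)
            h = [m[2] for m in upgma_linkage(D).merges]
            assert all(a <= b + 1e-15 for a, b in zip(h, h[1:]))


class TestFlatten:
    def test_extreme_thresholds(self):
        rng = np.random.default_rng(3)
        D = random_distance_matrix(rng, 6)
        dend = upgma_linkage(D)
        assert len(set(flatten_dendrogram(dend, 0.0))) == 6
        assert len(set(flatten_dendrogram(dend, 1.0))) == 1

    def test_three_leaf_example(self):
        D = np.array([[0, 0.2, 0.6], [0.2, 0, 0.8], [0.6, 0.8, 0]])
        labels = flatten_dendrogram(upgma_linkage(D), 0.4)
        assert labels[0] == labels[1] != labels[2]

    def test_labels_ordered_by_smallest_leaf(self):
        D = np.array([[0, 0.9, 0.1], [0.9, 0, 0.9], [0.1, 0.9, 0]])
        labels = flatten_dendrogram(upgma_linkage(D), 0.5)
        # leaf 0 seen first -> cluster 0; leaf 1 alone -> cluster 1
        assert list(labels) == [0, 1, 0]

    def test_nestedness(self):
        """Partitions at higher thresholds coarsen those at lower ones."""
        rng = np.random.default_rng(11)
        for _ in range(10):
            D = random_distance_matrix(rng, 9)
            dend = upgma_linkage(D)
            t1, t2 = sorted(rng.uniform(0, 1, size=2))
            lab1 = flatten_dendrogram(dend, t1)
            lab2 = flatten_dendrogram(dend, t2)
            mapping = {}
            for a, b in zip(lab1, lab2):
                assert mapping.setdefault(a, b) == b


class TestMergeSmallClusters:
    def make_three_clusters(self, profile_factory):
        # X near e1, Z near e3, Y between but closer to Z
        profiles = [
            profile_factory(("m", 1), 700, [10, 1, 0, 0]),
            profile_factory(("m", 2), 800, [10, 1, 0, 0]),
            profile_factory(("m", 3), 800, [0, 1, 6, 4]),
            profile_factory(("m", 4), 1000, [0, 0, 10, 1]),
            profile_factory(("m", 5), 1000, [0, 0, 10, 1]),
        ]
        labels = [0, 0, 1, 2, 2]  # X:1500, Y:800, Z:2000
        return profiles, assignment_from_labels(profiles, labels)

    def test_small_absorbed_by_nearest_large(self, profile_factory):
        profiles, assignment = self.make_three_clusters(profile_factory)
        merged = merge_small_clusters(assignment, profiles, 1000)
        assert merged.cluster_particle_counts == {0: 1500, 2: 2800}
        assert merged.labels[("m", 3)] == 2
        assert merged.remainder_id is None

    def test_no_op_when_all_large(self, profile_factory):
        profiles, assignment = self.make_three_clusters(profile_factory)
        merged = merge_small_clusters(assignment, profiles, 500)
        assert merged.labels == assignment.labels

    def test_all_small_pooled_into_remainder(self, profile_factory):
        profiles, assignment = self.make_three_clusters(profile_factory)
        merged = merge_small_clusters(assignment, profiles, 10_000)
        assert merged.remainder_id is not None
        assert len(merged.cluster_particle_counts) == 1
        assert merged.total_particles == assignment.total_particles

    def test_conserves_particles(self, profile_factory):
        profiles, assignment = self.make_three_clusters(profile_factory)
        for threshold in (1, 900, 1600, 10_000):
            merged = merge_small_clusters(assignment, profiles, threshold)
            assert merged.total_particles == assignment.total_particles

    def test_invalid_min_particles(self, profile_factory):
        profiles, assignment = self.make_three_clusters(profile_factory)
        with pytest.raises(ValueError):
            merge_small_clusters(assignment, profiles, 0)


class TestHomogeneity:
    def test_singleton_and_identical(self, profile_factory):
        p = profile_factory(("m", 1), 5, [1, 2, 3])
        assert cluster_homogeneity([p]) == 0.0
        q = profile_factory(("m", 2), 9, [1, 2, 3])
        assert cluster_homogeneity([p, q]) == pytest.approx(0.0, abs=1e-12)

    def test_mean_of_pairwise(self, profile_factory):
        # three profiles engineered so the mean is just the average of the
        # three pairwise distances, recomputed independently
        rng = np.random.default_rng(5)
        ps = [profile_factory(("m", i), 5, rng.uniform(0.01, 1, 4))
              for i in range(3)]
        expected = np.mean([
            cosine_distance(ps[i].distribution, ps[j].distribution)
            for i, j in [(0, 1), (0, 2), (1, 2)]
        ])
        assert cluster_homogeneity(ps) == pytest.approx(expected, abs=1e-12)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            cluster_homogeneity([])


class TestIteratePolymorphClustering:
    def test_one_hot_profiles_converge_immediately(self, profile_factory):
        profiles = [
            profile_factory(("m", i), 600, np.eye(4)[i % 2]) for i in range(6)
        ]
        calls = []

        def reclassify(keys, it):
            calls.append(keys)
            raise AssertionError("should not be called")

        assignment, log = iterate_polymorph_clustering(
            profiles, reclassify, ClusteringConfig(min_particles=1000)
        )
        assert calls == []
        assert len(assignment.cluster_particle_counts) == 2
        assert len(log) == 1 and log[0].reclassified == []

    def test_max_iterations_zero_returns_initial(self, profile_factory):
        profiles = [
            profile_factory(("m", i), 600, np.eye(4)[i % 2]) for i in range(6)
        ]
        assignment, log = iterate_polymorph_clustering(
            profiles, None, ClusteringConfig(max_iterations=0, min_particles=1)
        )
        assert log == []
        assert len(assignment.cluster_particle_counts) == 2

    def test_empty_input(self):
        assignment, log = iterate_polymorph_clustering(
            [], None, ClusteringConfig()
        )
        assert assignment.labels == {} and log == []

    def test_reclassify_failure_carries_context(self, profile_factory):
        rng = np.random.default_rng(2)
        profiles = [
            profile_factory(("m", i), 2000, rng.uniform(0.01, 1, 5))
            for i in range(8)
        ]

        def broken(keys, it):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="iteration 1"):
            iterate_polymorph_clustering(
                profiles, broken,
                ClusteringConfig(flatten_threshold=1.0,
                                 homogeneity_epsilon=0.0),
            )

    def test_two_polymorph_overlap_resolved_by_reclassification(self):
        """Overlapping initial profiles, separation-increasing reclassifier:
        the final labels match ground truth exactly."""
        from sklearn.metrics import adjusted_rand_score

        config = GeneratorConfig(
            n_polymorphs=2, assignment_noise=0.45, seed=3,
            min_profile_separation=0.7,
        )
        records, truth = generate_polymorph_dataset(config)
        profiles = profiles_from_records(records, config.n_classes)
        cc = ClusteringConfig(flatten_threshold=0.3, homogeneity_epsilon=0.1)
        assignment, log = iterate_polymorph_clustering(
            profiles, make_reclassifier(truth, seed=3), cc
        )
        keys = [p.filament_key for p in profiles]
        ari = adjusted_rand_score(
            truth.labels_for(keys), [assignment.labels[k] for k in keys]
        )
        assert ari == 1.0
        assert len(log) >= 1

    def test_audit_log_structure(self, default_dataset):
        config, records, truth = default_dataset
        profiles = profiles_from_records(records, config.n_classes)
        assignment, log = iterate_polymorph_clustering(
            profiles, make_reclassifier(truth, 1), ClusteringConfig()
        )
        for rec in log:
            assert rec.n_clusters == len(rec.cluster_sizes)
            assert set(rec.cluster_sizes) == set(rec.homogeneities)
            assert sum(rec.cluster_particles.values()) == sum(
                p.n_particles for p in profiles
            )
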