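"""SOM clustering, landmark matching, baselines and self-consistency."""

import numpy as np
import pytest

from cytoscaffold.data_model import ExpressionMatrix, ReferenceDataset
from cytoscaffold.errors import ConfigError, DataError
from cytoscaffold.scaffold import (
    annotate,
    baseline_knn,
    baseline_lda,
    compute_query_landmarks,
    compute_reference_landmarks,
    cosine_similarity,
    self_consistency_protocol,
)
from cytoscaffold.som import assign_to_nodes, train_som
from cytoscaffold.synthetic import generate_reference


class TestSom:
    def test_two_blobs_converge_to_blob_means(self, rng):
        a = rng.normal([0, 0], 0.05, size=(300, 2))
        b = rng.normal([5, 5], 0.05, size=(300, 2))
        X = np.vstack([a, b])
        som = train_som(X, rows=2, cols=1, seed=1)
        means = np.array([a.mean(axis=0), b.mean(axis=0)])
        # each codebook vector sits within 0.1 of one blob mean, both blobs hit
        d = np.linalg.norm(som.codebook[:, None] - means[None], axis=2)
        assert (d.min(axis=1) < 0.1).all()
        assert set(d.argmin(axis=1)) == {0, 1}

    def test_identical_cells_are_a_fixed_point(self):
        X = np.tile([1.5, -2.0, 3.0], (50, 1))
        som = train_som(X, rows=3, cols=3, seed=0)
        np.testing.assert_allclose(som.codebook, np.tile(X[0], (9, 1)), atol=1e-6)

    def test_same_seed_same_codebook(self, rng):
        X = rng.normal(size=(200, 5))
        c1 = train_som(X, rows=4, cols=4, seed=9).codebook
        c2 = train_som(X, rows=4, cols=4, seed=9).codebook
        np.testing.assert_array_equal(c1, c2)

    def test_assignment_matches_brute_force(self, rng):
        X = rng.normal(size=(500, 4))
        som = train_som(X, rows=5, cols=5, seed=2)
        cells = rng.normal(size=(1000, 4))
        got = assign_to_nodes(som, cells)
        brute = np.array(
            [
                int(np.argmin([np.sum((c - v) ** 2) for v in som.codebook]))
                for c in cells
            ]
        )
        np.testing.assert_array_equal(got, brute)

    def test_exact_codebook_match_and_tie_rule(self, rng):
        som = train_som(rng.normal(size=(100, 2)), rows=3, cols=2, seed=3)
        got = assign_to_nodes(som, som.codebook[4:5])
        assert got[0] == 4
        # equidistant construction: midpoint of two codebook vectors
        mid = (som.codebook[2] + som.codebook[5]) / 2
        d = np.linalg.norm(som.codebook - mid, axis=1)
        winners = np.flatnonzero(np.isclose(d, d.min()))
        assert assign_to_nodes(som, mid[None])[0] == winners[0]

    def test_dimension_mismatch_rejected(self, rng):
        som = train_som(rng.normal(size=(50, 3)), rows=2, cols=2, seed=0)
        with pytest.raises(DataError):
            assign_to_nodes(som, rng.normal(size=(5, 4)))


class TestLandmarks:
    def test_query_landmark_is_cluster_mean(self):
        X = np.array([[1.0, 1.0], [3.0, 3.0], [10.0, 0.0]])
        lm, occupied = compute_query_landmarks(X, np.array([0, 0, 7]))
        np.testing.assert_allclose(lm.profiles[0], [2.0, 2.0])
        np.testing.assert_allclose(lm.profiles[1], [10.0, 0.0])  # singleton
        assert list(occupied) == [0, 7]  # empty nodes produce no landmark
        assert list(lm.member_counts) == [2, 1]

    def test_occupied_node_count(self, rng):
        X = rng.normal(size=(300, 3))
        ids = rng.integers(0, 100, size=300)
        lm, occupied = compute_query_landmarks(X, ids)
        assert lm.profiles.shape[0] == np.unique(ids).size == occupied.size

    def test_reference_landmarks_are_type_means(self, rng):
        vals = np.vstack([rng.normal(0, 0.1, (40, 3)), rng.normal(5, 0.1, (60, 3))])
        labels = np.array(["a"] * 40 + ["b"] * 60, dtype=object)
        m = ExpressionMatrix(values=vals, marker_names=["x", "y", "z"], cell_labels=labels)
        lm = compute_reference_landmarks(ReferenceDataset(matrix=m), ["x", "y", "z"])
        assert lm.labels == ["a", "b"]
        np.testing.assert_allclose(lm.profiles[0], vals[:40].mean(axis=0))
        # permutation invariance
        perm = rng.permutation(100)
        m2 = ExpressionMatrix(
            values=vals[perm], marker_names=["x", "y", "z"], cell_labels=labels[perm]
        )
        lm2 = compute_reference_landmarks(ReferenceDataset(matrix=m2), ["x", "y", "z"])
        np.testing.assert_allclose(lm2.profiles, lm.profiles)


class TestCosine:
    @pytest.mark.parametrize(
        "u,v,expected",
        [
            ([1, 0], [1, 0], 1.0),
            ([1, 0], [0, 1], 0.0),
            ([1, 2, 3], [4, 5, 6], 32 / (np.sqrt(14) * np.sqrt(77))),
            ([1, 1], [-1, -1], -1.0),
        ],
    )
    def test_known_values(self, u, v, expected):
        assert cosine_similarity(u, v) == pytest.approx(expected, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(DataError):
            cosine_similarity([0, 0], [1, 0])


class TestAnnotate:
    def _ref_from_profiles(self, profiles, names, rng, n=200, sd=0.05):
        blocks = [p + rng.normal(0, sd, (n, len(p))) for p in profiles]
        labels = np.concatenate([[nm] * n for nm in names]).astype(object)
        m = ExpressionMatrix(
            values=np.vstack(blocks),
            marker_names=[f"m{i}" for i in range(profiles.shape[1])],
            cell_labels=labels,
        )
        return ReferenceDataset(matrix=m)

    def test_recovers_generating_labels(self, rng):
        profiles = np.array(
            [[4.0, 0.2, 0.1, 0.1], [0.1, 4.0, 0.2, 0.1], [0.1, 0.2, 4.0, 3.0]]
        )
        names = ["alpha", "beta", "gamma"]
        ref = self._ref_from_profiles(profiles, names, rng)
        q_labels = np.array(
            [names[i] for i in rng.integers(0, 3, size=600)], dtype=object
        )
        q_vals = np.array(
            [profiles[names.index(l)] + rng.normal(0, 0.05, 4) for l in q_labels]
        )
        query = ExpressionMatrix(values=q_vals, marker_names=ref.matrix.marker_names)
        res = annotate(query, ref, grid=(4, 4), per_sample=False, seed=7)
        assert (res.cell_labels == q_labels).mean() == 1.0

    def test_threshold_one_rejects_noisy_clusters(self, rng):
        profiles = np.array([[4.0, 0.2, 0.1, 0.1], [0.1, 4.0, 0.2, 0.1]])
        ref = self._ref_from_profiles(profiles, ["a", "b"], rng)
        query = ExpressionMatrix(
            values=rng.uniform(0, 4, (200, 4)), marker_names=ref.matrix.marker_names
        )
        res = annotate(query, ref, grid=(3, 3), per_sample=False, threshold=1.0, seed=1)
        assert set(res.cell_labels) == {"unassigned"}

    def test_single_cluster_on_reference_profile_scores_similarity_one(self, rng):
        profiles = np.array([[3.0, 1.0, 0.2], [0.2, 3.0, 1.0]])
        ref = self._ref_from_profiles(profiles, ["T", "U"], rng, sd=0.0)
        query = ExpressionMatrix(
            values=np.tile(profiles[0], (30, 1)), marker_names=ref.matrix.marker_names
        )
        res = annotate(query, ref, grid=(1, 1), per_sample=False, seed=0)
        assert set(res.cell_labels) == {"T"}
        assert res.cluster_best_similarity[0] == pytest.approx(1.0, abs=1e-12)

    def test_positive_scaling_leaves_assignments_unchanged(self, rng):
        profiles = np.array([[4.0, 0.2, 0.1, 0.1], [0.1, 4.0, 0.2, 0.1]])
        ref = self._ref_from_profiles(profiles, ["a", "b"], rng)
        query = ExpressionMatrix(
            values=np.vstack(
                [profiles[i] + rng.normal(0, 0.1, 4) for i in rng.integers(0, 2, 300)]
            ),
            marker_names=ref.matrix.marker_names,
        )
        r1 = annotate(query, ref, grid=(3, 3), per_sample=False, seed=5)
        scaled = ExpressionMatrix(
            values=query.values * 3.7, marker_names=query.marker_names
        )
        # SOM updates are linear in the data, so clusters scale with it and
        # cosine similarity ignores magnitude entirely.
        ref_scaled = ReferenceDataset(
            matrix=ExpressionMatrix(
                values=ref.matrix.values * 3.7,
                marker_names=ref.matrix.marker_names,
                cell_labels=ref.matrix.cell_labels,
            )
        )
        r2 = annotate(scaled, ref_scaled, grid=(3, 3), per_sample=False, seed=5)
        np.testing.assert_array_equal(r1.cell_labels, r2.cell_labels)
        np.testing.assert_allclose(r1.similarities, r2.similarities, atol=1e-9)

    def test_every_cell_gets_exactly_one_label(self, rng):
        profiles = np.array([[4.0, 0.2, 0.1], [0.1, 4.0, 0.2]])
        ref = self._ref_from_profiles(profiles, ["a", "b"], rng)
        query = ExpressionMatrix(
            values=rng.uniform(0, 4, (123, 3)), marker_names=ref.matrix.marker_names
        )
        res = annotate(query, ref, grid=(3, 3), per_sample=False, seed=2)
        assert res.cell_labels.shape == (123,)
        per_cluster = [
            int((res.cluster_ids == c).sum()) for c in np.unique(res.cluster_ids)
        ]
        assert len(per_cluster) == len(res.cluster_labels)
        assert sum(per_cluster) == 123
        assert all(lab in {"a", "b"} for lab in res.cell_labels)


class TestBaselines:
    def test_knn_one_point_per_class(self):
        train = np.array([[0.0, 0.0], [10.0, 10.0]])
        labels = np.array(["A", "B"], dtype=object)
        pred = baseline_knn(train, labels, np.array([[1.0, 1.0]]), k=1)
        assert pred[0] == "A"

    def test_knn_matches_brute_force_oracle(self, rng):
        train = rng.normal(size=(200, 3))
        labels = np.array([f"c{i % 3}" for i in range(200)], dtype=object)
        test = rng.normal(size=(50, 3))
        for k in (3, 10):
            got = baseline_knn(train, labels, test, k=k)
            for i, t in enumerate(test):
                d = np.linalg.norm(train - t, axis=1)
                order = np.argsort(d, kind="stable")[:k]
                votes = labels[order]
                uniq, counts = np.unique(votes.astype(str), return_counts=True)
                winners = set(uniq[counts == counts.max()])
                expect = next(str(l) for l in votes if str(l) in winners)
                assert got[i] == expect

    def test_knn_k_exceeds_training_size(self):
        with pytest.raises(DataError):
            baseline_knn(np.zeros((3, 2)), np.array(["a", "a", "b"]), np.zeros((1, 2)), k=5)

    def test_lda_on_well_separated_gaussians(self, rng):
        # 6 sigma separation: Bayes error ~ Phi(-3) ~ 0.13%, demand <= 5%
        a = rng.normal(0.0, 1.0, size=(500, 2))
        b = rng.normal(6.0, 1.0, size=(500, 2))
        X = np.vstack([a, b])
        y = np.array(["a"] * 500 + ["b"] * 500, dtype=object)
        test_a = rng.normal(0.0, 1.0, size=(500, 2))
        test_b = rng.normal(6.0, 1.0, size=(500, 2))
        pred = baseline_lda(X, y, np.vstack([test_a, test_b]))
        err = np.mean(pred != np.array(["a"] * 500 + ["b"] * 500, dtype=object))
        assert err <= 0.05

    def test_lda_single_class_rejected(self):
        with pytest.raises(DataError):
            baseline_lda(np.zeros((4, 2)), np.array(["a"] * 4), np.zeros((1, 2)))


class TestSelfConsistency:
    def test_perfect_separation_gives_perfect_f1(self, small_reference):
        spec, ref = small_reference
        reports = self_consistency_protocol(
            ref, backbone=list(spec.backbone_names), train_frac=0.8,
            methods=("scaffold",), grid=(6, 6), seed=1,
        )
        for d in reports["scaffold"].per_class.values():
            assert d["metrics"]["F1"] == pytest.approx(1.0)

    def test_half_split_variant_runs(self, small_reference):
        spec, ref = small_reference
        reports = self_consistency_protocol(
            ref, backbone=list(spec.backbone_names), train_frac=0.5,
            methods=("scaffold", "knn3"), grid=(6, 6), seed=2,
        )
        assert set(reports) == {"scaffold", "knn3"}
        assert reports["knn3"].macro["F1"] > 0.95

    def test_single_type_reference_rejected(self, rng):
        m = ExpressionMatrix(
            values=rng.normal(size=(100, 3)),
            marker_names=["a", "b", "c"],
            cell_labels=np.array(["only"] * 100, dtype=object),
        )
        with pytest.raises(DataError):
            self_consistency_protocol(ReferenceDataset(matrix=m))

    def test_bad_train_frac_rejected(self, small_reference):
        _, ref = small_reference
        with pytest.raises(ConfigError):
            self_consistency_protocol(ref, train_frac=1.5)
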