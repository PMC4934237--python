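"""K-means with fixed labeled centroids, LOOCV protocol, accuracy reporting."""

import numpy as np
import pytest

from synglove import (
    ConfusionMatrix,
    KMeansConfig,
    accuracy_report,
    kmeans_fixed_init,
    loocv_recognition,
    make_grasp_generators,
    sample_grasp_panel,
)


def test_samples_equal_to_centroids_converge_immediately(rng):
    centroids = rng.normal(size=(4, 19))
    assignments, final, n_iter = kmeans_fixed_init(centroids.copy(), centroids)
    np.testing.assert_array_equal(assignments, np.arange(4))
    np.testing.assert_allclose(final, centroids)


def test_separated_1d_clusters_are_a_fixed_point():
    samples = np.array([[0.0], [1.0], [10.0], [11.0]])
    init = np.array([[0.5], [10.5]])
    assignments, final, n_iter = kmeans_fixed_init(samples, init,
                                                   KMeansConfig(n_clusters=2))
    np.testing.assert_array_equal(assignments, [0, 0, 1, 1])
    np.testing.assert_allclose(final, init)


def test_lloyd_fixed_point_properties(rng):
    """Convergence means: centroids are cluster means and every sample sits
    with its nearest centroid, so no single-sample reassignment under the
    final centroids can lower the squared-distance cost; the final
    within-cluster cost never exceeds that of the initial assignment."""
    for _ in range(10):
        samples = rng.normal(size=(8, 3))
        init = rng.normal(size=(2, 3))
        assignments, centroids, _ = kmeans_fixed_init(samples, init,
                                                      KMeansConfig(n_clusters=2))

        def cost(assign, cents):
            return float(sum(((samples[i] - cents[assign[i]]) ** 2).sum()
                             for i in range(len(samples))))

        # centroids are the means of their members
        for j in range(2):
            members = samples[assignments == j]
            if len(members):
                np.testing.assert_allclose(centroids[j], members.mean(axis=0))
        # nearest-centroid optimality: no single move helps under fixed centroids
        base = cost(assignments, centroids)
        for i in range(len(samples)):
            moved = assignments.copy()
            moved[i] = 1 - moved[i]
            assert base <= cost(moved, centroids) + 1e-9
        # monotone improvement over the initial assignment's configuration
        init_assign = ((samples[:, None, :] - init[None]) ** 2).sum(2).argmin(1)
        assert base <= cost(init_assign, init) + 1e-9


def test_kmeans_deterministic_and_order_independent(rng):
    samples = rng.normal(size=(30, 19))
    init = rng.normal(size=(3, 19))
    a1, c1, _ = kmeans_fixed_init(samples, init, KMeansConfig(n_clusters=3))
    a2, c2, _ = kmeans_fixed_init(samples, init, KMeansConfig(n_clusters=3))
    np.testing.assert_array_equal(a1, a2)
    np.testing.assert_allclose(c1, c2)
    perm = rng.permutation(len(samples))
    ap, cp, _ = kmeans_fixed_init(samples[perm], init, KMeansConfig(n_clusters=3))
    np.testing.assert_array_equal(ap, a1[perm])
    np.testing.assert_allclose(cp, c1)


def test_matches_sklearn_lloyd(rng):
    """Cross-check against an independent Lloyd implementation (scikit-learn)."""
    from sklearn.cluster import KMeans

    samples = rng.normal(size=(60, 5)) + np.repeat(
        rng.normal(scale=8, size=(3, 5)), 20, axis=0
    )
    init = samples[[0, 20, 40]]
    ours, centroids, _ = kmeans_fixed_init(samples, init, KMeansConfig(n_clusters=3))
    sk = KMeans(n_clusters=3, init=init, n_init=1, max_iter=100, tol=0,
                algorithm="lloyd").fit(samples)
    np.testing.assert_array_equal(ours, sk.labels_)
    np.testing.assert_allclose(centroids, sk.cluster_centers_, atol=1e-8)


def test_empty_cluster_keeps_its_centroid():
    samples = np.array([[0.0], [0.2]])
    init = np.array([[0.1], [100.0]])
    assignments, final, _ = kmeans_fixed_init(samples, init, KMeansConfig(n_clusters=2))
    np.testing.assert_array_equal(assignments, [0, 0])
    assert final[1, 0] == pytest.approx(100.0)  # identity preserved


def test_dimension_mismatch_rejected(rng):
    with pytest.raises(ValueError):
        kmeans_fixed_init(rng.normal(size=(5, 3)), rng.normal(size=(2, 4)))


def _noiseless_panel():
    gens = make_grasp_generators(seed=1, separation=10.0,
                                 within_synergy_sd=(0.0,), within_residual_sd=0.0)
    return sample_grasp_panel(gens, n_subjects=5, n_reps=3,
                              subject_jitter_sd=0.0, seed=2)


def test_loocv_noiseless_panel_is_perfect():
    panel = _noiseless_panel()
    results = loocv_recognition(panel)
    assert len(results) == 5
    for _, cm in results:
        np.testing.assert_array_equal(cm.counts, 12 * np.eye(8, dtype=int))
        relative, absolute = accuracy_report(cm)
        assert absolute == 100.0
        assert all(r == 100.0 for r in relative)


def test_loocv_confusion_structure():
    gens = make_grasp_generators(seed=3, separation=3.0)
    panel = sample_grasp_panel(gens, n_subjects=5, n_reps=3, seed=4)
    for subject, cm in loocv_recognition(panel):
        assert cm.counts.sum() == 96          # 4 remaining subjects x 3 reps x 8 grasps
        np.testing.assert_array_equal(cm.counts.sum(axis=1), np.full(8, 12))


def test_loocv_requires_two_subjects():
    panel = _noiseless_panel()
    solo = type(panel)(
        poses=panel.poses[panel.subject_id == 1],
        subject_id=panel.subject_id[panel.subject_id == 1],
        grasp_label=panel.grasp_label[panel.subject_id == 1],
        repetition=panel.repetition[panel.subject_id == 1],
    )
    with pytest.raises(ValueError):
        loocv_recognition(solo)


def test_accuracy_report_known_tables():
    cm = ConfusionMatrix(counts=12 * np.eye(8, dtype=int))
    relative, absolute = accuracy_report(cm)
    assert absolute == 100.0

    counts = 12 * np.eye(8, dtype=int)
    counts[1, 1], counts[1, 5] = 10, 2
    counts[2, 2], counts[2, 0] = 11, 1
    counts[5, 5], counts[5, 3] = 11, 1
    relative, absolute = accuracy_report(ConfusionMatrix(counts=counts))
    assert relative[1] == 83.33
    assert relative[2] == 91.67
    assert absolute == 95.83


def test_accuracy_is_count_weighted_mean_of_relatives(rng):
    counts = rng.integers(0, 10, size=(8, 8)) + np.eye(8, dtype=int)
    cm = ConfusionMatrix(counts=counts)
    relative, absolute = accuracy_report(cm, decimals=None)
    weights = counts.sum(axis=1)
    assert absolute == pytest.approx(float(np.average(relative, weights=weights)))


def test_accuracy_report_empty_row_rejected():
    counts = np.zeros((3, 3), dtype=int)
    counts[0, 0] = counts[1, 1] = 1
    with pytest.raises(ValueError):
        accuracy_report(ConfusionMatrix(counts=counts))
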