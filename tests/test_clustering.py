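"""Mixture fits, CH-index model selection, and outlier exclusion."""

import numpy as np
import pytest
from sklearn.metrics import calinski_harabasz_score

import hotspotter as h
from hotspotter.clustering import ClusterComponent, InsufficientDataError


def ch_brute_force(points, centroids, labels):
    """Independent direct evaluation of the CH formula, term by term."""
    points = np.asarray(points, dtype=float)
    K = len(centroids)
    N = len(points)
    c = points.mean(axis=0)
    between = sum(
        (labels == k).sum() * np.dot(centroids[k] - c, centroids[k] - c)
        for k in range(K)
    )
    within = sum(
        np.dot(p - centroids[labels[i]], p - centroids[labels[i]])
        for i, p in enumerate(points)
    )
    return (between / (K - 1)) / (within / (N - K))


class TestCHIndex:
    def test_hand_worked_two_cluster_example(self):
        """{(0,0),(1,0)} vs {(10,0),(11,0)}: between=100, within=0.5, CH=200."""
        pts = np.array([[0, 0], [1, 0], [10, 0], [11, 0]], dtype=float)
        labels = np.array([0, 0, 1, 1])
        cents = np.array([[0.5, 0], [10.5, 0]])
        assert h.ch_index(pts, cents, labels) == pytest.approx(200.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(30, 2))
        labels = rng.integers(0, 3, size=30)
        cents = np.stack([pts[labels == k].mean(axis=0) for k in range(3)])
        a = h.ch_index(pts, cents, labels)
        b = h.ch_index(7.3 * pts, 7.3 * cents, labels)
        assert b == pytest.approx(a, rel=1e-12)

    def test_matches_brute_force_on_random_instances(self):
        """100 random partitions (n ≤ 50, K ≤ 5) agree to 1e-10 relative."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = int(rng.integers(10, 51))
            K = int(rng.integers(2, 6))
            pts = rng.normal(scale=10, size=(n, 2))
            labels = rng.integers(0, K, size=n)
            labels[:K] = np.arange(K)  # every cluster non-empty
            cents = np.stack([pts[labels == k].mean(axis=0) for k in range(K)])
            mine = h.ch_index(pts, cents, labels)
            ref = ch_brute_force(pts, cents, labels)
            assert mine == pytest.approx(ref, rel=1e-10)

    def test_matches_sklearn_on_centroid_partitions(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(40, 2))
        labels = rng.integers(0, 4, size=40)
        labels[:4] = np.arange(4)
        cents = np.stack([pts[labels == k].mean(axis=0) for k in range(4)])
        assert h.ch_index(pts, cents, labels) == pytest.approx(
            calinski_harabasz_score(pts, labels), rel=1e-10
        )

    def test_degenerate_inputs(self):
        pts = np.array([[0.0, 0], [0, 0], [1, 1]])
        with pytest.raises(ValueError, match="K ≥ 2"):
            h.ch_index(pts, np.array([[0.0, 0]]), np.zeros(3, dtype=int))
        pts4 = np.array([[0.0, 0], [0, 1], [1, 1], [2, 2]])
        with pytest.raises(ValueError, match="empty"):
            h.ch_index(pts4, np.array([[0.0, 0], [1, 1], [2, 2]]),
                       np.array([0, 0, 1, 1]))
        # zero within-dispersion → +inf sentinel
        pts2 = np.array([[0, 0], [0, 0], [5, 5], [5, 5]], dtype=float)
        cents = np.array([[0, 0], [5, 5]], dtype=float)
        assert h.ch_index(pts2, cents, np.array([0, 0, 1, 1])) == np.inf


class TestFitGMM:
    def test_single_component_is_sample_moments(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(loc=(3, -2), scale=(2, 1), size=(400, 2))
        m = h.fit_gmm(pts, K=1, n_restarts=1, seed=0)
        assert np.allclose(m.components[0].mean, pts.mean(axis=0), atol=1e-8)
        assert np.allclose(
            m.components[0].covariance, np.cov(pts.T, bias=True), rtol=1e-3, atol=1e-3
        )

    def test_two_separated_blobs_recovered(self):
        rng = np.random.default_rng(3)
        a = rng.normal((0, 0), 1.0, size=(100, 2))
        b = rng.normal((30, 0), 1.0, size=(100, 2))
        m = h.fit_gmm(np.vstack([a, b]), K=2, n_restarts=5, seed=1)
        means = sorted(c.mean.tolist() for c in m.components)
        assert np.linalg.norm(np.array(means[0]) - a.mean(axis=0)) < 0.5
        assert np.linalg.norm(np.array(means[1]) - b.mean(axis=0)) < 0.5

    def test_same_seed_reproduces_model(self, smooth_ribbon):
        _, _, pts = smooth_ribbon
        a = h.fit_gmm(pts, K=4, n_restarts=3, seed=5)
        b = h.fit_gmm(pts, K=4, n_restarts=3, seed=5)
        assert np.array_equal(a.assignments, b.assignments)
        for ca, cb in zip(a.components, b.components):
            assert np.array_equal(ca.mean, cb.mean)

    def test_insufficient_data_rejected(self):
        with pytest.raises(InsufficientDataError):
            h.fit_gmm(np.zeros((5, 2)), K=3)

    def test_labels_are_one_based(self, smooth_ribbon):
        _, _, pts = smooth_ribbon
        m = h.fit_gmm(pts, K=3, n_restarts=2, seed=0)
        assert m.assignments.min() >= 1 and m.assignments.max() <= 3


class TestSelect:
    def test_planted_four_component_scene_selects_four(self, smooth_ribbon):
        _, _, pts = smooth_ribbon
        model, ch_by_k = h.select_components(pts, 2, 10, n_restarts=5, seed=2)
        assert model.K == 4
        assert set(ch_by_k) == set(range(2, 11))

    def test_recovered_means_near_planted_centers(self, paired_scene, smooth_ribbon):
        _, truth = paired_scene
        _, _, pts = smooth_ribbon
        model, _ = h.select_components(pts, 2, 10, n_restarts=5, seed=2)
        centers = np.array([c["center"] for c in truth["planted_components"]])
        sds = [c["sd"] for c in truth["planted_components"]]
        used = set()
        for comp in model.components:
            d = np.linalg.norm(centers - comp.mean, axis=1)
            j = int(np.argmin(d))
            assert d[j] < 0.5 * sds[j]
            assert j not in used  # distinct planted centers
            used.add(j)

    def test_single_blob_is_flagged_low_contrast(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(150, 2))
        model, ch_by_k = h.select_components(pts, 2, 8, n_restarts=3, seed=4)
        assert model.low_contrast
        finite = [v for v in ch_by_k.values() if np.isfinite(v)]
        assert max(finite) < 2.0 * np.median(finite)

    def test_degenerate_k_range_returns_that_model(self, smooth_ribbon):
        _, _, pts = smooth_ribbon
        model, ch_by_k = h.select_components(pts, 3, 3, n_restarts=2, seed=0)
        assert model.K == 3 and list(ch_by_k) == [3]


class TestMahalanobis:
    IDENT = ClusterComponent(1.0, np.zeros(2), np.eye(2))

    def test_identity_covariance_is_euclidean(self):
        assert h.mahalanobis_distance((3.0, 4.0), self.IDENT) == pytest.approx(5.0)

    def test_distance_at_mean_is_zero(self):
        assert h.mahalanobis_distance((0.0, 0.0), self.IDENT) == 0.0

    def test_anisotropic_covariance(self):
        comp = ClusterComponent(1.0, np.zeros(2), np.diag([4.0, 1.0]))
        assert h.mahalanobis_distance((2.0, 0.0), comp) == pytest.approx(1.0)

    def test_singular_covariance_raises(self):
        comp = ClusterComponent(1.0, np.zeros(2), np.zeros((2, 2)))
        with pytest.raises(np.linalg.LinAlgError):
            h.mahalanobis_distance((1.0, 1.0), comp)


class TestOutliers:
    def test_extreme_thresholds(self, smooth_ribbon):
        _, _, pts = smooth_ribbon
        m = h.fit_gmm(pts, K=4, n_restarts=3, seed=1)
        assert not h.flag_outliers(pts, m, threshold=np.inf).any()
        strict = h.flag_outliers(pts, m, threshold=0.0)
        at_mean = np.array([
            any(np.allclose(p, c.mean) for c in m.components) for p in pts
        ])
        assert np.array_equal(strict, ~at_mean)

    def test_monotone_in_threshold(self, smooth_ribbon):
        _, _, pts = smooth_ribbon
        m = h.fit_gmm(pts, K=4, n_restarts=3, seed=1)
        rng = np.random.default_rng(0)
        extra = rng.uniform(-80, 80, size=(1000, 2))
        prev = h.flag_outliers(extra, m, threshold=0.5)
        for thr in (1.0, 2.0, 3.0, 5.0):
            cur = h.flag_outliers(extra, m, threshold=thr)
            assert not (cur & ~prev).any()  # raising never flags new points
            prev = cur

    def test_planted_far_synapse_is_unique_outlier(self, smooth_ribbon):
        _, _, pts = smooth_ribbon
        far = np.vstack([pts, [[400.0, 400.0]]])
        m = h.fit_gmm(pts, K=4, n_restarts=3, seed=1)
        mask = h.flag_outliers(far, m, threshold=3.0)
        assert mask[-1]
        assert mask[:-1].sum() <= 0.1 * len(pts)  # planted point dominates

    def test_assignments_invariant_under_component_relabeling(self, smooth_ribbon):
        """Permuting component order permutes labels consistently."""
        _, _, pts = smooth_ribbon
        m = h.fit_gmm(pts, K=4, n_restarts=3, seed=1)
        perm = np.array([2, 0, 3, 1])
        permuted = h.ClusterModel(
            K=4,
            components=[m.components[j] for j in perm],
            assignments=m.assignments.copy(),
            ch_index=m.ch_index,
            log_likelihood=m.log_likelihood,
            outlier_mask=m.outlier_mask.copy(),
            seed=m.seed,
        )
        a = h.flag_outliers(pts, m, 3.0)
        b = h.flag_outliers(pts, permuted, 3.0)
        assert np.array_equal(a, b)  # outlier mask ignores component order


class TestComposition:
    def _model_for(self, n, labels, K):
        return h.ClusterModel(
            K=K,
            components=[ClusterComponent(1 / K, np.zeros(2), np.eye(2))] * K,
            assignments=np.asarray(labels),
            ch_index=0.0,
            log_likelihood=0.0,
            outlier_mask=np.zeros(n, dtype=bool),
            seed=0,
        )

    @staticmethod
    def _ribbon(sid, pre_type):
        return h.SynapseRecord(sid, f"pre-{sid}", "c", "ribbon", 0, 0, 0, pre_type)

    def test_small_cluster_proportions(self):
        syn = [self._ribbon("a", "BC_DB5"), self._ribbon("b", "BC_DB5"),
               self._ribbon("c", "BC_DB4")]
        comp = h.cluster_composition(syn, self._model_for(3, [1, 1, 1], 1))
        assert comp[1] == pytest.approx({"BC_DB4": 1 / 3, "BC_DB5": 2 / 3})

    def test_uniform_type_gives_proportion_one(self):
        syn = [self._ribbon(str(i), "BC_giant") for i in range(6)]
        comp = h.cluster_composition(syn, self._model_for(6, [1, 1, 2, 2, 3, 3], 3))
        assert all(v == {"BC_giant": 1.0} for v in comp.values())

    def test_outliers_excluded_and_empty_cluster_reported(self):
        syn = [self._ribbon("a", "BC_DB5"), self._ribbon("b", "BC_DB4")]
        model = self._model_for(2, [1, 2], 2)
        model.outlier_mask[1] = True
        comp = h.cluster_composition(syn, model)
        assert comp[1] == {"BC_DB5": 1.0} and comp[2] == {}

    def test_configured_type_proportions_recovered_per_cluster(self, paired_scene,
                                                               smooth_ribbon):
        """Per-cluster type proportions match the generator's multinomial
        within 3 binomial SDs."""
        _, truth = paired_scene
        _, ribbon, pts = smooth_ribbon
        model, _ = h.select_components(pts, 2, 10, n_restarts=5, seed=2)
        h.flag_outliers(pts, model, 3.0)
        comp = h.cluster_composition(ribbon, model)
        expected = truth["type_proportions"]
        for k, props in comp.items():
            n_k = sum(
                1 for lbl, o in zip(model.assignments, model.outlier_mask)
                if lbl == k and not o
            )
            for t, p in expected.items():
                se = np.sqrt(p * (1 - p) / n_k)
                assert abs(props.get(t, 0.0) - p) <= 3 * se + 1e-12
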