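import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhizospec.bandselect import ROISet
from rhizospec.segment import (
    SKEWNESS_FAIL_THRESHOLD,
    binary_skewness,
    evaluate_segmentation,
    fuzzy_cmeans,
    segment_fuzzy_cmeans,
    segment_kmeans,
    segment_svm,
    segment_threshold,
)


class TestBinarySkewness:
    @given(p=st.floats(0.01, 0.99))
    @settings(max_examples=30, deadline=None)
    def test_closed_form_holds_exactly(self, p):
        n = 4000
        k = int(round(p * n))
        if k in (0, n):
            return
        mask = np.zeros(n, dtype=bool)
        mask[:k] = True
        p_eff = k / n
        expected = (1 - 2 * p_eff) / np.sqrt(p_eff * (1 - p_eff))
        assert binary_skewness(mask) == pytest.approx(expected, rel=1e-10)

    def test_half_mask_zero_skew(self):
        mask = np.zeros((10, 10), bool)
        mask[:5] = True
        assert binary_skewness(mask) == pytest.approx(0.0, abs=1e-12)


class TestEvaluate:
    def _mask(self, p, shape=(100, 100)):
        m = np.zeros(shape, bool)
        m.ravel()[: int(p * m.size)] = True
        return m

    def test_symmetric_mask_fails(self):
        from rhizospec.segment import SegmentationResult

        res = SegmentationResult(self._mask(0.5), "x")
        rec = evaluate_segmentation(res)
        assert rec["failed"]

    def test_sparse_mask_passes(self):
        from rhizospec.segment import SegmentationResult

        res = SegmentationResult(self._mask(0.05), "x")
        rec = evaluate_segmentation(res)
        # Bernoulli closed form: 0.9 / sqrt(0.0475) = 4.13 > 2.5
        assert rec["skewness"] == pytest.approx(0.9 / np.sqrt(0.0475), rel=1e-6)
        assert not rec["failed"]

    def test_failure_boundary_near_p_0_1096(self):
        # (1-2p)/sqrt(p(1-p)) = 2.5  =>  p = (10.25 - sqrt(64.0625)) / 20.5
        p_star = (10.25 - np.sqrt(10.25**2 - 4 * 10.25 * 1)) / (2 * 10.25)
        assert p_star == pytest.approx(0.1096, abs=1e-4)
        from rhizospec.segment import SegmentationResult

        just_fail = evaluate_segmentation(
            SegmentationResult(self._mask(p_star + 0.002, (1000, 100)), "x")
        )
        just_pass = evaluate_segmentation(
            SegmentationResult(self._mask(p_star - 0.002, (1000, 100)), "x")
        )
        assert just_fail["failed"] and not just_pass["failed"]


class TestThreshold:
    def test_two_delta_image(self):
        rng = np.random.default_rng(0)
        img = np.zeros((50, 50))
        sel = rng.random((50, 50)) < 0.1
        img[sel] = 1.0
        res = segment_threshold(img, n_classes=2)
        np.testing.assert_array_equal(res.mask, sel)

    def test_otsu_matches_brute_force_on_toy_histogram(self):
        # 8-level toy image; oracle: exhaustive between-class variance search
        rng = np.random.default_rng(1)
        levels = np.array([0, 1, 2, 3, 4, 5, 6, 7], dtype=float)
        counts = np.array([50, 80, 60, 5, 3, 2, 40, 30])
        img = np.repeat(levels, counts)
        rng.shuffle(img)
        img = img.reshape(10, 27)

        best_t, best_var = None, -1.0
        for t in range(1, 8):
            lo, hi = img[img < t], img[img >= t]
            if lo.size == 0 or hi.size == 0:
                continue
            w0, w1 = lo.size / img.size, hi.size / img.size
            var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
            if var > best_var:
                best_var, best_t = var, t
        from skimage.filters import threshold_multiotsu

        # nbins=8 aligns histogram bins with the 8 discrete levels
        thr = threshold_multiotsu(img, classes=2, nbins=8)[0]
        lab_oracle = img >= best_t
        lab_otsu = img > thr
        np.testing.assert_array_equal(lab_oracle, lab_otsu)

    def test_three_class_root_is_bright_cluster(self):
        rng = np.random.default_rng(2)
        img = rng.normal(0.3, 0.01, (60, 60))  # soil mode
        img[10:50, 10:20] = rng.normal(0.5, 0.01, (40, 10))  # mixed
        img[20:40, 40:43] = rng.normal(0.8, 0.01, (20, 3))  # root
        res = segment_threshold(img, n_classes=3)
        expected = np.zeros((60, 60), bool)
        expected[20:40, 40:43] = True
        # all root pixels captured, at most a couple of mixed strays
        assert res.mask[expected].all()
        assert (res.mask & ~expected).sum() <= 2

    def test_constant_image_fails_without_exception(self):
        res = segment_threshold(np.full((20, 20), 0.5))
        assert res.failed and not res.mask.any()


class TestKMeans:
    def test_two_cluster_toy(self):
        img = np.array([[0.0, 0.0], [10.0, 10.0]])
        res = segment_kmeans(img, k=2, seed=0)
        assert res.mask.sum() == 2
        assert res.mask[1].all()  # 10s are mode-distant? mode=0 cluster larger? equal
        # {0,0} and {10,10}: equal counts; mode bin holds the 0s, so root = 10s

    def test_matches_exhaustive_min_sse_partition(self):
        # 6 points, k=2: brute-force over all 2-partitions
        pts = np.array([0.0, 0.2, 0.4, 5.0, 5.1, 9.0])

        def sse(groups):
            return sum(((g - g.mean()) ** 2).sum() for g in groups if len(g))

        best = None
        for assign in itertools.product([0, 1], repeat=6):
            if len(set(assign)) < 2:
                continue
            groups = [pts[np.array(assign) == c] for c in (0, 1)]
            s = sse(groups)
            if best is None or s < best[0]:
                best = (s, assign)
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(pts.reshape(-1, 1))
        oracle = np.array(best[1])
        got = km.labels_
        same = np.all(got == oracle) or np.all(got == 1 - oracle)
        assert same
        assert km.inertia_ == pytest.approx(best[0], rel=1e-9)

    def test_same_seed_identical_mask(self):
        rng = np.random.default_rng(3)
        img = rng.random((40, 40))
        img[5:30, 5:8] += 2.0
        m1 = segment_kmeans(img, k=3, seed=11).mask
        m2 = segment_kmeans(img, k=3, seed=11).mask
        np.testing.assert_array_equal(m1, m2)


class TestFuzzyCMeans:
    def _blobs(self, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.0, 0.05, size=(100, 2))
        b = rng.normal(5.0, 0.05, size=(100, 2))
        return np.vstack([a, b])

    def test_memberships_sum_to_one(self):
        u, _, _ = fuzzy_cmeans(self._blobs(), c=2, seed=0)
        np.testing.assert_allclose(u.sum(axis=1), 1.0, atol=1e-10)

    def test_separated_blobs_high_membership(self):
        x = self._blobs()
        u, centroids, _ = fuzzy_cmeans(x, c=2, seed=1)
        own = u.max(axis=1)
        assert (own > 0.99).mean() > 0.99

    def test_objective_nonincreasing(self):
        _, _, trace = fuzzy_cmeans(self._blobs(seed=5), c=3, seed=2)
        assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))

    def test_coincident_centroid_membership_one(self):
        x = np.array([[0.0], [0.0], [1.0], [2.0]])
        u, _, _ = fuzzy_cmeans(x, c=2, seed=0)
        np.testing.assert_allclose(u.sum(axis=1), 1.0)

    def test_segmentation_deterministic(self):
        rng = np.random.default_rng(4)
        img = rng.normal(0.3, 0.02, (30, 30))
        img[5:25, 10:13] = rng.normal(0.8, 0.02, (20, 3))
        m1 = segment_fuzzy_cmeans(img, seed=7).mask
        m2 = segment_fuzzy_cmeans(img, seed=7).mask
        np.testing.assert_array_equal(m1, m2)


class TestSvm:
    def _scene(self, seed=0):
        rng = np.random.default_rng(seed)
        img = rng.normal(0.3, 0.03, (80, 80))
        truth = np.zeros((80, 80), bool)
        truth[10:70, 20:24] = True
        truth[30:34, 10:70] = True
        img[truth] = rng.normal(0.8, 0.03, truth.sum())
        return img, truth

    def _rois(self, truth, seed=0, n=40):
        rng = np.random.default_rng(seed)
        root = np.argwhere(truth)
        soil = np.argwhere(~truth)
        return ROISet(
            root[rng.choice(len(root), n, replace=False)],
            soil[rng.choice(len(soil), n, replace=False)],
        )

    def test_separable_training_accuracy_one(self):
        img, truth = self._scene()
        res = segment_svm(img, self._rois(truth))
        assert res.meta["train_accuracy"] == 1.0

    def test_label_swap_swaps_polarity(self):
        img, truth = self._scene()
        rois = self._rois(truth)
        swapped = ROISet(rois.soil_pixels, rois.root_pixels)
        m1 = segment_svm(img, rois).mask
        m2 = segment_svm(img, swapped).mask
        np.testing.assert_array_equal(m1, ~m2)

    def test_small_roi_rejected(self):
        img, truth = self._scene()
        with pytest.raises(ValueError, match="at least 20"):
            segment_svm(img, self._rois(truth, n=10))

    def test_recovers_truth_with_sparse_labels(self):
        # 0.6%-of-pixels labelling fraction
        img, truth = self._scene(seed=1)
        n = max(int(0.006 * truth.size / 2), 20)
        res = segment_svm(img, self._rois(truth, seed=2, n=n))
        iou = (res.mask & truth).sum() / (res.mask | truth).sum()
        assert iou > 0.9


def test_threshold_on_scene_recovers_length(ci_scene, ci_cube):
    from rhizospec.postprocess import estimate_root_length, remove_noise_objects

    band = ci_cube.band_index(1450.0)
    img = ci_cube.data[:, :, band]
    res = segment_threshold(img, n_classes=3)
    rm = remove_noise_objects(res.mask, 10, 20, mm_per_px=0.1)
    length = estimate_root_length(rm)
    assert length == pytest.approx(ci_scene.skeleton_length_cm, rel=0.15)
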