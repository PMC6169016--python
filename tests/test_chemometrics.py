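import numpy as np
import pytest

from rhizospec.chemometrics import (
    RadialClassSpec,
    allocation_matrix,
    fit_decay_model,
    label_radial_classes,
    map_decay_image,
    prepare_chemometric_features,
    select_decay_feature,
    train_radial_model,
    DecayModel,
)
from rhizospec.hypercube import HyperCube
from rhizospec.postprocess import RootMask


class TestRadialLabels:
    def test_one_px_root_all_class_one(self):
        mask = np.zeros((10, 30), bool)
        mask[5, 5:25] = True
        labels = label_radial_classes(mask)
        assert set(labels[mask]) == {1}
        assert np.all(labels[~mask] == 0)

    def test_three_px_root_center_vs_flanks(self):
        mask = np.zeros((11, 40), bool)
        mask[4:7, 5:35] = True
        labels = label_radial_classes(mask)
        center = labels[5, 10:30]
        flank_up = labels[4, 10:30]
        flank_dn = labels[6, 10:30]
        assert set(center) == {1}  # on the skeleton: 0 mm
        # flanking rows: 1 px = 0.1 mm from the axis -> class 2 (0.1-0.3 mm)
        assert set(flank_up) == {2}
        assert set(flank_dn) == {2}

    def test_disk_reaches_class_eight(self):
        from skimage.draw import disk as draw_disk

        mask = np.zeros((64, 64), bool)
        rr, cc = draw_disk((32, 32), 15)
        mask[rr, cc] = True
        labels = label_radial_classes(mask)
        assert labels.max() >= 7  # rim pixels >= 1.1 mm from the center skeleton
        assert 1 in labels[mask]

    def test_class_monotone_in_exact_distance(self):
        # oracle: brute-force all-pairs distance to skeleton pixels
        from skimage.morphology import skeletonize

        rng = np.random.default_rng(0)
        mask = np.zeros((40, 40), bool)
        mask[8:30, 15:24] = True
        labels = label_radial_classes(mask)
        skel = skeletonize(mask)
        skel_pts = np.argwhere(skel)
        for r, c in np.argwhere(mask)[rng.choice(mask.sum(), 50, replace=False)]:
            d = np.min(np.hypot(skel_pts[:, 0] - r, skel_pts[:, 1] - c)) * 0.1
            expected = int(np.digitize(d, RadialClassSpec().edges_mm)) + 1
            assert labels[r, c] == expected

    def test_empty_mask(self):
        assert label_radial_classes(np.zeros((5, 5), bool)).sum() == 0


class TestPrepareFeatures:
    def _cube_mask(self, rank1=False, seed=0):
        rng = np.random.default_rng(seed)
        wl = np.linspace(1000, 1700, 20)
        mask = np.zeros((12, 12), bool)
        mask[3:9, 3:9] = True
        if rank1:
            # sharp peak survives ALS correction; positive scaling commutes
            # with ALS, so corrected spectra stay exactly rank-1
            amp = 0.5 + rng.random((12, 12, 1))
            peak = np.exp(-0.5 * ((np.arange(20) - 10) / 1.5) ** 2)
            data = amp * peak[None, None, :]
        else:
            data = rng.random((12, 12, 20))
        cube = HyperCube(data.astype(np.float32), wl)
        return cube, RootMask(mask)

    def test_rank1_pc1_dominates(self):
        cube, mask = self._cube_mask(rank1=True)
        _, evr, _ = prepare_chemometric_features(cube, mask)
        assert evr[0] > 0.999

    def test_row_count_is_root_pixel_count(self):
        cube, mask = self._cube_mask()
        scores, _, pixels = prepare_chemometric_features(cube, mask)
        assert scores.shape == (int(mask.mask.sum()), 5)
        assert len(pixels) == int(mask.mask.sum())

    def test_scores_match_eigendecomposition_oracle(self):
        cube, mask = self._cube_mask(seed=3)
        from rhizospec.pretreat import als_baseline

        scores, _, pixels = prepare_chemometric_features(cube, mask)
        spectra = cube.data[pixels[:, 0], pixels[:, 1]].astype(np.float64)
        _, corrected = als_baseline(spectra)
        centered = corrected - corrected.mean(axis=0)
        vals, vecs = np.linalg.eigh(centered.T @ centered / (len(centered) - 1))
        order = np.argsort(vals)[::-1][:5]
        oracle = centered @ vecs[:, order]
        for c in range(5):
            sign = np.sign(scores[:, c] @ oracle[:, c]) or 1.0
            np.testing.assert_allclose(scores[:, c], sign * oracle[:, c], atol=1e-6)

    def test_too_few_bands_rejected(self):
        cube = HyperCube(np.zeros((4, 4, 3), np.float32), [1000.0, 1100.0, 1200.0])
        with pytest.raises(ValueError, match="fewer bands"):
            prepare_chemometric_features(cube, np.ones((4, 4), bool))


class TestRadialModel:
    def _separable(self, n_per_class=60, n_classes=4, seed=0):
        rng = np.random.default_rng(seed)
        feats, labels = [], []
        for c in range(1, n_classes + 1):
            center = np.zeros(5)
            center[0] = c * 10.0
            feats.append(center + 0.1 * rng.normal(size=(n_per_class, 5)))
            labels.append(np.full(n_per_class, c))
        return np.vstack(feats), np.concatenate(labels)

    def test_separable_training_r_one(self):
        x, y = self._separable()
        model = train_radial_model(x, y, split_seed=1)
        assert model.r_train == pytest.approx(1.0)
        assert model.r_valid == pytest.approx(1.0)

    def test_permuted_labels_near_zero_r(self):
        rng = np.random.default_rng(5)
        x, y = self._separable(n_per_class=2500, seed=2)
        y = rng.permutation(y)
        model = train_radial_model(x, y, split_seed=1)
        assert abs(model.r_valid) < 0.1

    def test_allocation_columns_sum_100(self):
        x, y = self._separable(seed=3)
        model = train_radial_model(x, y, split_seed=0)
        sums = model.allocation_matrix.drop(index="pct_total_pixels").sum(axis=0)
        np.testing.assert_allclose(sums.to_numpy(), 100.0, atol=0.2)

    def test_small_class_dropped(self):
        x, y = self._separable()
        x = np.vstack([x, [[99, 0, 0, 0, 0]]])
        y = np.concatenate([y, [9]])
        model = train_radial_model(x, y, split_seed=0)
        assert 9 not in model.allocation_matrix.columns


class TestAllocationMatrix:
    def test_identity_prediction(self):
        y = np.repeat([1, 2, 3], 10)
        df = allocation_matrix(y, y, np.array([1, 2, 3]))
        np.testing.assert_allclose(np.diag(df.iloc[:3].to_numpy()), 100.0)
        np.testing.assert_allclose(df.loc["pct_total_pixels"].sum(), 100.0)


class TestDecayFeature:
    def _series(self, seed=0):
        # only two bands change over time; their difference carries the signal
        rng = np.random.default_rng(seed)
        wl = np.linspace(1000, 1700, 15)
        out = {}
        for day, shift in [(0.0, 0.0), (100.0, 0.03)]:
            spectra = 0.5 + 0.01 * rng.normal(size=(2000, 15))
            spectra[:, 4] -= shift  # "water" band drops
            spectra[:, 11] += shift * 0.5  # "structural" band rises
            out[day] = spectra
        return out, wl

    def test_designed_pair_selected(self):
        series, wl = self._series()
        model = select_decay_feature(series, wl, transforms=("raw",), kinds=("pair_difference",))
        assert set(model.wavelengths_nm) == {wl[4], wl[11]}

    def test_identical_series_error(self):
        spectra = np.full((50, 15), 0.5)
        wl = np.linspace(1000, 1700, 15)
        with pytest.raises(ValueError, match="no discriminative"):
            select_decay_feature({0.0: spectra, 10.0: spectra}, wl)


class TestDecayFit:
    def test_exact_exponential_recovered(self):
        x = np.linspace(0.1, 1.0, 6)
        t = 5.0 * np.exp(2.0 * x)
        model = fit_decay_model(x, t)
        assert model.a == pytest.approx(5.0, abs=1e-9)
        assert model.b == pytest.approx(2.0, abs=1e-9)
        assert model.r2 == pytest.approx(1.0, abs=1e-12)

    def test_log_linear_closed_form_equivalence(self):
        rng = np.random.default_rng(8)
        x = rng.random(8)
        t = np.exp(1.0 + 0.5 * x) * rng.uniform(0.95, 1.05, 8)
        model = fit_decay_model(x, t)
        # closed-form OLS on (x, ln t)
        lx = np.log(t)
        b = np.cov(x, lx, bias=True)[0, 1] / np.var(x)
        a = np.exp(lx.mean() - b * x.mean())
        assert model.b == pytest.approx(b, abs=1e-10)
        assert model.a == pytest.approx(a, abs=1e-10)

    def test_monte_carlo_b_recovery_paper_days(self):
        # sampling days {14, 28, 47, 94, 101, 201}, 5% noise on t, 200 seeds
        days = np.array([14.0, 28.0, 47.0, 94.0, 101.0, 201.0])
        b_true, a_true = 2.0, 5.0
        x_clean = np.log(days / a_true) / b_true
        errs = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            t_noisy = days * (1 + 0.05 * rng.normal(size=6))
            model = fit_decay_model(x_clean, np.maximum(t_noisy, 1e-3))
            errs.append(abs(model.b - b_true) / b_true)
        assert np.median(errs) < 0.10

    def test_holdout_days_excluded_from_fit(self):
        days = np.array([14.0, 28.0, 47.0, 94.0, 101.0, 201.0])
        x = np.log(days / 5.0) / 2.0
        x[1] += 5.0  # corrupt a holdout point; fit must not move
        model = fit_decay_model(x, days, holdout=[28.0, 101.0])
        assert model.b == pytest.approx(2.0, abs=1e-9)
        assert len(model.holdout_residuals) == 2

    def test_constant_feature_degenerate(self):
        model = fit_decay_model(np.ones(5), np.arange(1.0, 6.0))
        assert model.degenerate

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fit_decay_model(np.arange(4.0), np.array([-1.0, 1.0, 2.0, 3.0]))

    def test_alternative_direction_recovers_k(self):
        t = np.array([14.0, 28.0, 47.0, 94.0, 201.0])
        k_true = 0.02
        x = 0.3 + 0.5 * np.exp(-k_true * t)
        model = fit_decay_model(x, t, direction="x_of_t")
        assert model.k == pytest.approx(k_true, rel=1e-6)


class TestMapDecay:
    def _fitted_model(self, wl):
        m = DecayModel(transform="raw", kind="single", wavelengths_nm=(wl[3],))
        m.a, m.b = 5.0, 2.0
        return m

    def test_uniform_spectra_predict_training_day(self):
        wl = np.linspace(1000, 1700, 10)
        model = self._fitted_model(wl)
        x28 = np.log(28.0 / model.a) / model.b
        data = np.zeros((6, 6, 10), np.float32)
        data[:, :, 3] = x28
        cube = HyperCube(data, wl)
        mask = np.zeros((6, 6), bool)
        mask[2:4, 2:4] = True
        img = map_decay_image(cube, mask, model)
        np.testing.assert_allclose(img[mask], 28.0, rtol=1e-5)

    def test_background_is_nodata(self):
        wl = np.linspace(1000, 1700, 10)
        model = self._fitted_model(wl)
        cube = HyperCube(np.full((5, 5, 10), 0.2, np.float32), wl)
        mask = np.zeros((5, 5), bool)
        mask[1, 1] = True
        img = map_decay_image(cube, mask, model)
        assert np.isnan(img[~mask]).all()
        assert np.isfinite(img[mask]).all()

    def test_missing_wavelength_error(self):
        wl = np.linspace(1000, 1700, 10)
        model = DecayModel(transform="raw", kind="single", wavelengths_nm=(2500.0,))
        model.a, model.b = 1.0, 1.0
        cube = HyperCube(np.zeros((4, 4, 10), np.float32), wl)
        with pytest.raises(ValueError, match="outside cube range"):
            map_decay_image(cube, np.ones((4, 4), bool), model)
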