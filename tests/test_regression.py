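"""Model fitting, metrics, and wavelength selection."""

import numpy as np
import pytest

from hypertrait import (
    RegressionModel,
    SpectralDataset,
    compute_metrics,
    evaluate,
    fit_latent,
    fit_ml,
    fit_ridge,
    refit_on_selection,
    select_by_coefficients,
    select_by_features,
    split_by_replicate,
)
from hypertrait.errors import InvalidSplitError, UnsupportedModelError
from hypertrait.regression import NITROGEN_FEATURE_WINDOWS, WATER_FEATURE_WINDOWS


def _dataset(n=60, bands=30, seed=0, noise=0.0, rank=None):
    g = np.random.default_rng(seed)
    if rank is None:
        X = g.normal(size=(n, bands))
    else:
        scores = g.normal(size=(n, rank))
        loadings = g.normal(size=(rank, bands))
        X = scores @ loadings
    beta = g.normal(size=bands)
    y = X @ beta + 5.0 + noise * g.normal(size=n)
    return SpectralDataset(
        X=X,
        grid=np.linspace(400, 1000, bands),
        y=y,
        replicate=np.tile(np.arange(1, 7), n // 6),
        trait="water",
    )


class TestSplitByReplicate:
    def test_last_third_validation_fraction(self):
        ds = _dataset(n=60)
        train, val = split_by_replicate(ds, {5, 6})
        assert val.n_samples == 20 and train.n_samples == 40
        assert set(np.unique(val.replicate)) == {5, 6}

    def test_partitions_disjoint_and_exhaustive(self):
        ds = _dataset(n=36)
        train, val = split_by_replicate(ds, {3})
        assert set(train.sample_id) & set(val.sample_id) == set()
        assert len(set(train.sample_id) | set(val.sample_id)) == ds.n_samples

    def test_exhaustive_or_unknown_replicates_rejected(self):
        ds = _dataset(n=36)
        with pytest.raises(InvalidSplitError):
            split_by_replicate(ds, set(np.unique(ds.replicate)))
        with pytest.raises(InvalidSplitError):
            split_by_replicate(ds, {99})
        with pytest.raises(InvalidSplitError):
            split_by_replicate(ds, set())


class TestLatentModels:
    def test_single_latent_factor_recovered(self):
        ds = _dataset(n=60, bands=25, rank=1)
        train, val = split_by_replicate(ds, {5, 6})
        model = fit_latent(train, "plsr", seed=1)
        assert model.hyperparams["n_components"] == 1
        m = evaluate(model, val)
        assert m.r2 >= 1 - 1e-6
        assert m.rmse == pytest.approx(0.0, abs=1e-6)

    def test_pcr_at_full_rank_equals_ols(self):
        ds = _dataset(n=60, bands=10, noise=0.5)
        train, _ = split_by_replicate(ds, {6})
        model = fit_latent(train, "pcr", n_components=10, max_components=10, seed=1)
        # OLS oracle
        A = np.column_stack([np.ones(train.n_samples), train.X])
        coef, *_ = np.linalg.lstsq(A, train.y, rcond=None)
        ols_pred = A @ coef
        np.testing.assert_allclose(model.predict(train.X), ols_pred, atol=1e-8)

    @pytest.mark.parametrize("method", ["plsr", "pcr"])
    def test_collapsed_beta_matches_estimator_path(self, method):
        """beta/intercept collapse reproduces the latent-score prediction."""
        ds = _dataset(n=48, bands=20, noise=1.0, seed=3)
        train, val = split_by_replicate(ds, {6})
        model = fit_latent(train, method, n_components=4, seed=2)
        if method == "plsr":
            from sklearn.cross_decomposition import PLSRegression

            est = PLSRegression(n_components=4, scale=False).fit(train.X, train.y)
            direct = est.predict(val.X).reshape(-1)
        else:
            from sklearn.decomposition import PCA
            from sklearn.linear_model import LinearRegression

            pca = PCA(n_components=4).fit(train.X)
            lr = LinearRegression().fit(pca.transform(train.X), train.y)
            direct = lr.predict(pca.transform(val.X))
        np.testing.assert_allclose(model.predict(val.X), direct, atol=1e-10)

    def test_needs_more_samples_than_components(self):
        ds = _dataset(n=6, bands=20)
        with pytest.raises(ValueError):
            fit_latent(ds, "plsr", max_components=10)


class TestRidge:
    def test_lambda_to_zero_approaches_ols(self):
        ds = _dataset(n=60, bands=8, noise=0.3, seed=4)
        train, _ = split_by_replicate(ds, {6})
        model = fit_ridge(train, lambda_grid=np.array([1e-8]), n_repeats=1)
        A = np.column_stack([np.ones(train.n_samples), train.X])
        coef, *_ = np.linalg.lstsq(A, train.y, rcond=None)
        np.testing.assert_allclose(model.predict(train.X), A @ coef, atol=1e-4)

    def test_coefficient_norm_shrinks_with_lambda(self):
        ds = _dataset(n=60, bands=15, noise=0.3, seed=5)
        train, _ = split_by_replicate(ds, {6})
        norms = [
            np.linalg.norm(fit_ridge(train, lambda_grid=np.array([lam]), n_repeats=1).beta)
            for lam in (0.1, 1.0, 10.0, 100.0)
        ]
        assert all(a >= b for a, b in zip(norms, norms[1:]))

    def test_default_grid_has_100_candidates(self):
        ds = _dataset(n=36, bands=5, noise=0.5, seed=6)
        train, _ = split_by_replicate(ds, {6})
        model = fit_ridge(train, n_repeats=1, cv_folds=3)
        assert model.rmsep_curve.size == 100
        assert model.hyperparams["lambda"] == pytest.approx(
            np.round(np.arange(0.1, 10.01, 0.1), 10)[np.argmin(model.rmsep_curve)]
        )

    def test_empty_grid_rejected(self):
        ds = _dataset(n=36, bands=5)
        with pytest.raises(ValueError):
            fit_ridge(ds, lambda_grid=np.array([]))


class TestMLModels:
    def test_rf_seed_determinism(self):
        ds = _dataset(n=36, bands=10, noise=1.0, seed=7)
        a = fit_ml(ds, "rf", seed=3, n_estimators=50)
        b = fit_ml(ds, "rf", seed=3, n_estimators=50)
        np.testing.assert_array_equal(a.predict(ds.X), b.predict(ds.X))

    def test_svr_flat_target_within_epsilon(self):
        ds = _dataset(n=36, bands=10, seed=8)
        ds.y = np.full(ds.n_samples, 7.0)
        model = fit_ml(ds, "svr")
        assert np.all(np.abs(model.predict(ds.X) - 7.0) <= 0.1 + 1e-9)

    def test_rf_overfits_train_relative_to_validation(self):
        ds = _dataset(n=72, bands=25, noise=3.0, seed=9)
        train, val = split_by_replicate(ds, {5, 6})
        model = fit_ml(train, "rf", seed=1, n_estimators=100)
        assert evaluate(model, train).r2 > evaluate(model, val).r2

    def test_ml_models_have_no_beta(self):
        ds = _dataset(n=36, bands=10, seed=10)
        model = fit_ml(ds, "svr")
        assert model.beta is None and not model.is_linear
        with pytest.raises(UnsupportedModelError):
            select_by_coefficients(model)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            fit_ml(_dataset(n=36), "boost")


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = compute_metrics(y, y)
        assert m.r2 == pytest.approx(1.0)
        assert m.rmse == 0.0
        assert np.isinf(m.rpd) and "zero-rmse" in m.flags

    def test_constant_predictor_flagged(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        m = compute_metrics(y, np.full(5, y.mean()))
        assert m.r2 == 0.0
        assert "constant-prediction" in m.flags
        # rmse uses n denominator, sd uses n-1: rpd = sqrt(n/(n-1))
        assert m.rpd == pytest.approx(np.sqrt(5 / 4))

    def test_rpd_arithmetic(self):
        # construct y, yhat with sd(y)=4.5.. simpler: scale a known case
        g = np.random.default_rng(30)
        y = g.normal(size=400)
        y = (y - y.mean()) / y.std(ddof=1) * 4.5
        yhat = y + 3.0 * np.sign(np.arange(400) % 2 - 0.5)  # rmse exactly 3
        m = compute_metrics(y, yhat)
        assert m.rmse == pytest.approx(3.0)
        assert m.rpd == pytest.approx(4.5 / 3.0)

    def test_matches_hand_rolled_loop(self):
        g = np.random.default_rng(31)
        y = g.normal(70, 5, size=37)
        yhat = y + g.normal(0, 2, size=37)
        m = compute_metrics(y, yhat)
        sq = sum((b - a) ** 2 for a, b in zip(y, yhat))
        rmse = (sq / len(y)) ** 0.5
        ybar = sum(y) / len(y)
        sd = (sum((v - ybar) ** 2 for v in y) / (len(y) - 1)) ** 0.5
        assert m.rmse == pytest.approx(rmse, abs=1e-12)
        assert m.rpd == pytest.approx(sd / rmse, abs=1e-12)
        # ratio form of the determination coefficient
        yhbar = sum(yhat) / len(yhat)
        ratio = sum((v - yhbar) ** 2 for v in yhat) / sum((v - ybar) ** 2 for v in y)
        assert m.r2_ratio == pytest.approx(ratio, abs=1e-12)

    def test_sample_order_invariance(self):
        g = np.random.default_rng(32)
        y = g.normal(size=50)
        yhat = y + g.normal(0, 0.5, size=50)
        perm = g.permutation(50)
        a = compute_metrics(y, yhat)
        b = compute_metrics(y[perm], yhat[perm])
        assert a.r2 == pytest.approx(b.r2) and a.rmse == pytest.approx(b.rmse)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.array([1.0]), np.array([1.0]))


class TestSelectByCoefficients:
    def _linear_model(self, beta, grid=None):
        beta = np.asarray(beta, dtype=float)
        grid = np.arange(beta.size, dtype=float) if grid is None else grid
        return RegressionModel(method="plsr", grid=grid, beta=beta, intercept=0.0)

    def test_440_bands_at_30pct_gives_132(self):
        model = self._linear_model(np.random.default_rng(1).normal(size=440))
        sel = select_by_coefficients(model, fraction=0.30)
        assert sel.indices.size == 132

    def test_small_count_rounding(self):
        model = self._linear_model(np.arange(10.0) + 1)
        sel = select_by_coefficients(model, fraction=0.3)
        assert sel.indices.size == 3
        np.testing.assert_array_equal(sel.indices, [7, 8, 9])  # largest |beta|

    def test_all_equal_beta_keeps_lowest_wavelength_prefix(self):
        model = self._linear_model(np.full(10, 0.5))
        sel = select_by_coefficients(model, fraction=0.3)
        np.testing.assert_array_equal(sel.indices, [0, 1, 2])

    def test_rank_by_absolute_value(self):
        model = self._linear_model(np.array([0.1, -5.0, 0.2, 4.0, -0.3]))
        sel = select_by_coefficients(model, fraction=0.4)
        np.testing.assert_array_equal(sel.indices, [1, 3])

    @pytest.mark.parametrize("n,fraction", [(440, 0.3), (448, 0.3), (731, 0.3), (17, 0.5)])
    def test_retained_count_is_rounded_fraction(self, n, fraction):
        model = self._linear_model(np.random.default_rng(2).normal(size=n))
        sel = select_by_coefficients(model, fraction=fraction)
        assert sel.indices.size == int(np.floor(fraction * n + 0.5))


class TestSelectByFeatures:
    def test_water_970_window(self):
        w = {fw.center: (fw.lo, fw.hi) for fw in WATER_FEATURE_WINDOWS}
        assert w[970] == (950, 990)
        assert w[1425] == (1400, 1450)  # the broad O-H band

    def test_nitrogen_1500_window(self):
        w = {fw.center: (fw.lo, fw.hi) for fw in NITROGEN_FEATURE_WINDOWS}
        assert w[1500] == (1480, 1520)

    def test_most_windows_are_40nm_wide(self):
        for fw in WATER_FEATURE_WINDOWS:
            if fw.center != 1425:
                assert fw.hi - fw.lo == 40 and fw.lo == fw.center - 20
        for fw in NITROGEN_FEATURE_WINDOWS:
            assert fw.hi - fw.lo == 40 and fw.lo == fw.center - 20

    def test_water_band_count_on_1nm_vnir_grid(self):
        """Brute-force union of the sub-1000 nm water windows on a 1 nm grid."""
        grid = np.arange(400.0, 1001.0)
        sel = select_by_features(grid, "water")
        brute = set()
        for fw in WATER_FEATURE_WINDOWS:
            brute |= {w for w in grid if fw.lo <= w <= fw.hi}
        assert sel.indices.size == len(brute) == 254

    def test_unknown_trait_rejected(self):
        with pytest.raises(ValueError):
            select_by_features(np.arange(400.0, 1000.0), "chlorophyll")


class TestRefitOnSelection:
    def test_full_selection_identical_to_unselected_fit(self):
        ds = _dataset(n=60, bands=20, noise=0.5, seed=12)
        train, val = split_by_replicate(ds, {5, 6})
        from hypertrait.regression import WavelengthSelection

        all_sel = WavelengthSelection(
            indices=np.arange(20), wavelengths=ds.grid, method="coef_fraction"
        )
        model_full = fit_latent(train, "plsr", n_components=5, seed=3)
        model_sel, (mt, mv) = refit_on_selection(
            train, val, all_sel, method="plsr", n_components=5, seed=3
        )
        assert mv.r2 == pytest.approx(evaluate(model_full, val).r2, abs=1e-10)

    def test_sparse_signal_recovered_from_its_bands(self):
        g = np.random.default_rng(13)
        n, bands = 72, 40
        X = g.normal(size=(n, bands))
        signal_bands = np.arange(10, 20)
        beta = np.zeros(bands)
        beta[signal_bands] = g.normal(size=10)
        y = X @ beta + 0.1 * g.normal(size=n)
        ds = SpectralDataset(
            X=X, grid=np.linspace(400, 1000, bands), y=y,
            replicate=np.tile(np.arange(1, 7), 12), trait="water",
        )
        train, val = split_by_replicate(ds, {5, 6})
        from hypertrait.regression import WavelengthSelection

        sel = WavelengthSelection(
            indices=signal_bands, wavelengths=ds.grid[signal_bands], method="feature_windows"
        )
        full = fit_latent(train, "plsr", seed=4)
        _, (_, mv_sel) = refit_on_selection(train, val, sel, seed=4)
        # restricting to the signal-carrying bands loses (essentially) nothing
        assert mv_sel.r2 >= evaluate(full, val).r2 - 0.02

    def test_empty_selection_rejected(self):
        ds = _dataset(n=36, bands=10)
        train, val = split_by_replicate(ds, {6})
        from hypertrait.regression import WavelengthSelection

        empty = WavelengthSelection(indices=np.array([], dtype=int),
                                    wavelengths=np.array([]), method="coef_fraction")
        with pytest.raises(ValueError):
            refit_on_selection(train, val, empty)
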