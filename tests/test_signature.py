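import warnings

import numpy as np
import pytest

from painsense import signature as sg


def make_linear_data(rng, n, p, n_signal=10, noise=1.0):
    X = rng.standard_normal((n, p))
    w = np.zeros(p)
    w[:n_signal] = rng.standard_normal(n_signal)
    y = X @ w + noise * rng.standard_normal(n)
    return X, y


class TestSplit:
    def test_paper_sizes(self):
        disc, hold = sg.split_discovery_holdout(399, 0.5, seed=0)
        assert {len(disc), len(hold)} == {199, 200}

    def test_reproducible_and_exhaustive(self):
        a1, b1 = sg.split_discovery_holdout(50, 0.4, seed=3)
        a2, b2 = sg.split_discovery_holdout(50, 0.4, seed=3)
        np.testing.assert_array_equal(a1, a2)
        assert sorted(np.concatenate([a1, b1])) == list(range(50))
        assert np.intersect1d(a1, b1).size == 0

    def test_errors(self):
        with pytest.raises(ValueError):
            sg.split_discovery_holdout(100, 1.5)
        with pytest.raises(ValueError):
            sg.split_discovery_holdout(4, 0.5)


class TestEvaluate:
    def test_perfect(self):
        rep = sg.evaluate(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.r_squared == pytest.approx(1.0)

    def test_mean_prediction_zero(self):
        y = np.array([1.0, 2, 3, 4])
        rep = sg.evaluate(y, np.full(4, y.mean()))
        assert rep.r_squared == pytest.approx(0.0)
        assert np.isnan(rep.pearson_r)

    def test_reversed_direct_value(self):
        rep = sg.evaluate(np.array([1.0, 2, 3]), np.array([3.0, 2, 1]))
        assert rep.r_squared == pytest.approx(1 - 8 / 2)

    def test_r2_equals_r_squared_for_ls_affine_fit(self, rng):
        y = rng.standard_normal(40)
        x = 0.6 * y + rng.standard_normal(40)
        b = np.polyfit(x, y, 1)
        y_hat = np.polyval(b, x)
        rep = sg.evaluate(y, y_hat)
        assert rep.r_squared == pytest.approx(rep.pearson_r**2, abs=1e-10)

    def test_r2_differs_otherwise(self, rng):
        y = rng.standard_normal(40)
        y_hat = 0.3 * y + 5.0  # correlated but biased
        rep = sg.evaluate(y, y_hat)
        assert rep.r_squared < rep.pearson_r**2 - 0.5


class TestFitLassoPcr:
    def test_ols_limit(self, rng):
        # n > p, lambda -> 0: in-sample predictions match OLS
        X, y = make_linear_data(rng, 300, 100, noise=0.5)
        model, _ = sg.fit_lasso_pcr(X, y, lambda_grid=[1e-6], seed=0)
        preds = sg.predict(model, X)
        design = np.column_stack([np.ones(300), X])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        ols = design @ beta
        rms = np.sqrt(np.mean((preds - ols) ** 2))
        assert rms < 1e-3

    def test_permuted_labels_null(self, rng):
        X, y = make_linear_data(rng, 100, 200, noise=0.5)
        r2s = []
        for rep in range(5):
            perm = rng.permutation(100)
            _, report = sg.fit_lasso_pcr(
                X, y[perm], lambda_grid=sg.default_lambda_grid(15),
                seed=rep)
            r2s.append(report.r_squared)
        assert np.mean(r2s) < 0.05

    def test_zero_variance_voxels_dropped(self, rng):
        X, y = make_linear_data(rng, 60, 30, noise=0.5)
        X[:, 7] = 2.5
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            model, _ = sg.fit_lasso_pcr(X, y,
                                        lambda_grid=sg.default_lambda_grid(10),
                                        seed=0)
        assert not model.kept[7]
        assert model.voxel_weights[7] == 0.0

    def test_null_model_warning(self, rng):
        X = rng.standard_normal((50, 10))
        y = rng.standard_normal(50)
        with pytest.warns(RuntimeWarning, match="null model"):
            sg.fit_lasso_pcr(X, y, lambda_grid=[1e6], seed=0)

    def test_errors(self, rng):
        with pytest.raises(ValueError):
            sg.fit_lasso_pcr(rng.standard_normal((9, 4)),
                             rng.standard_normal(9))
        with pytest.raises(ValueError):
            sg.fit_lasso_pcr(rng.standard_normal((20, 4)),
                             rng.standard_normal(20), lambda_grid=[-1.0])

    def test_component_basis_orthonormal(self, rng):
        X, y = make_linear_data(rng, 60, 40, noise=0.5)
        model, _ = sg.fit_lasso_pcr(X, y,
                                    lambda_grid=sg.default_lambda_grid(10),
                                    seed=1)
        V = model.component_basis
        np.testing.assert_allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-8)

    def test_lambda_in_grid(self, rng):
        X, y = make_linear_data(rng, 60, 40, noise=0.5)
        grid = sg.default_lambda_grid(12)
        model, _ = sg.fit_lasso_pcr(X, y, lambda_grid=grid, seed=1)
        assert model.lam in grid


class TestBackprojection:
    @pytest.mark.parametrize("n,p", [(60, 40), (40, 80)])
    def test_identity(self, rng, n, p):
        X, y = make_linear_data(rng, n, p, noise=0.5)
        model, _ = sg.fit_lasso_pcr(X, y,
                                    lambda_grid=sg.default_lambda_grid(10),
                                    seed=2)
        w, c = sg.backproject_weights(model)
        new = rng.standard_normal((50, p))
        np.testing.assert_allclose(new @ w + c, sg.predict(model, new),
                                   atol=1e-8)

    def test_all_zero_coefs_flat_map(self, rng):
        X = rng.standard_normal((50, 10))
        y = rng.standard_normal(50) + 4.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model, _ = sg.fit_lasso_pcr(X, y, lambda_grid=[1e6], seed=0)
        w, c = sg.backproject_weights(model)
        np.testing.assert_allclose(w, 0.0, atol=1e-12)
        assert c == pytest.approx(y.mean())

    def test_save_load_round_trip(self, rng, tmp_path):
        X, y = make_linear_data(rng, 40, 27, noise=0.5)
        model, _ = sg.fit_lasso_pcr(X, y,
                                    lambda_grid=sg.default_lambda_grid(10),
                                    seed=3)
        mask = np.zeros((3, 3, 3), bool)
        mask.ravel()[:27] = True
        affine = np.eye(4)
        sg.save_signature(model, mask, affine, tmp_path / "sig")
        w, c, _, _ = sg.load_signature_weights(tmp_path / "sig")
        new = rng.standard_normal((20, 27))
        np.testing.assert_allclose(new @ w + c, sg.predict(model, new),
                                   atol=1e-5)


class TestLearningCurve:
    def test_sizes_echoed_and_small_skipped(self, rng):
        X, y = make_linear_data(rng, 80, 20, noise=0.5)
        lc = sg.learning_curve(X, y, sizes=[5, 20, 40], reps=2, seed=0,
                               lambda_grid=sg.default_lambda_grid(5))
        np.testing.assert_array_equal(lc.train_sizes, [20, 40])
        assert np.all(np.isfinite(lc.mean_r2))
        assert np.all(lc.sd_r2 >= 0)
        assert lc.reps == 2

    def test_too_large_size_errors(self, rng):
        X, y = make_linear_data(rng, 50, 10)
        with pytest.raises(ValueError):
            sg.learning_curve(X, y, sizes=[45], reps=1,
                              lambda_grid=[1.0])

    def test_determinism(self, rng):
        X, y = make_linear_data(rng, 80, 15, noise=0.5)
        a = sg.learning_curve(X, y, sizes=[30], reps=3, seed=5,
                              lambda_grid=sg.default_lambda_grid(5))
        b = sg.learning_curve(X, y, sizes=[30], reps=3, seed=5,
                              lambda_grid=sg.default_lambda_grid(5))
        np.testing.assert_array_equal(a.mean_r2, b.mean_r2)


class TestCovariateAdjustedFit:
    def test_zero_effect_covariates_close_to_unadjusted(self, rng):
        X, y = make_linear_data(rng, 120, 40, noise=1.0)
        cov = rng.standard_normal((120, 2))  # independent of everything
        grid = sg.default_lambda_grid(10)
        _, plain = sg.fit_lasso_pcr(X, y, lambda_grid=grid, seed=0)
        _, adj = sg.covariate_adjusted_fit(X, y, cov, lambda_grid=grid,
                                           seed=0)
        assert abs(plain.r_squared - adj.r_squared) < 0.15

    def test_covariates_generating_y(self, rng):
        X = rng.standard_normal((100, 30))
        cov = rng.standard_normal((100, 2))
        y = cov @ np.array([2.0, -1.0]) + 0.01 * rng.standard_normal(100)
        _, rep = sg.covariate_adjusted_fit(
            X, y, cov, lambda_grid=sg.default_lambda_grid(10), seed=0)
        assert rep.r_squared < 0.1

    def test_rank_deficient_raises(self, rng):
        X, y = make_linear_data(rng, 50, 10)
        c = rng.standard_normal(50)
        with pytest.raises(ValueError, match="rank-deficient"):
            sg.covariate_adjusted_fit(X, y, np.column_stack([c, 2 * c]),
                                      lambda_grid=[1.0])

    def test_site_effect_removal_improves_trait_recovery(self, rng):
        # an injected dataset shift lets the unadjusted model predict the
        # site component of y; the adjusted model should track the true
        # trait s more closely
        diffs = []
        for seed in range(3):
            rg = np.random.default_rng(seed)
            n, p = 150, 60
            s = rg.standard_normal(n)
            site = np.repeat([0.0, 1.0], n // 2)
            X = np.outer(s, np.concatenate([np.ones(10), np.zeros(p - 10)]))
            X += rg.standard_normal((n, p))
            X += 4.0 * site[:, None] * (rg.uniform(size=p) > 0.5)
            y = s + 3.0 * site + 0.5 * rg.standard_normal(n)
            grid = sg.default_lambda_grid(10)
            plain_model, _ = sg.fit_lasso_pcr(X, y, lambda_grid=grid, seed=0)
            adj_model, _ = sg.covariate_adjusted_fit(X, y, site[:, None],
                                                     lambda_grid=grid, seed=0)
            design = np.column_stack([np.ones(n), site])
            beta_X, *_ = np.linalg.lstsq(design, X, rcond=None)
            X_res = X - design @ beta_X
            r_plain = np.corrcoef(sg.predict(plain_model, X), s)[0, 1]
            r_adj = np.corrcoef(sg.predict(adj_model, X_res), s)[0, 1]
            diffs.append(r_adj - r_plain)
        assert np.mean(diffs) > 0.0


class TestBehaviorLasso:
    def test_single_predictive_feature(self, rng):
        y = rng.standard_normal(120)
        feat = 0.8 * y + 0.6 * rng.standard_normal(120)
        model, rep = sg.fit_behavior_lasso(feat[:, None], y, seed=0)
        univ = np.corrcoef(feat, y)[0, 1] ** 2
        assert rep.r_squared > univ - 0.2

    def test_all_noise_features(self, rng):
        F = rng.standard_normal((80, 12))
        y = rng.standard_normal(80)
        _, rep = sg.fit_behavior_lasso(F, y, seed=0)
        assert rep.r_squared <= 0.05

    def test_huge_lambda_shrinks_to_mean(self, rng):
        F = rng.standard_normal((50, 5))
        y = rng.standard_normal(50) + 2.0
        model, _ = sg.fit_behavior_lasso(F, y, lambda_grid=[1e7], seed=0)
        np.testing.assert_allclose(model.coefs, 0.0, atol=1e-12)
        np.testing.assert_allclose(model.predict(F), y.mean())

    def test_no_features_errors(self, rng):
        with pytest.raises(ValueError):
            sg.fit_behavior_lasso(np.empty((30, 0)), rng.standard_normal(30))

    def test_median_imputation(self, rng):
        F = rng.standard_normal((60, 3))
        y = F[:, 0] + 0.3 * rng.standard_normal(60)
        F_missing = F.copy()
        F_missing[5, 1] = np.nan
        model, rep = sg.fit_behavior_lasso(F_missing, y, seed=0)
        assert np.isfinite(rep.r_squared)


class TestStacking:
    @staticmethod
    def _two_block_data(rng, n=150, p=60, q=5):
        """Independent signal in maps and behavior blocks."""
        g = rng.standard_normal(n)
        h = rng.standard_normal(n)
        X = np.outer(g, np.concatenate([np.ones(8), np.zeros(p - 8)]))
        X += 0.7 * rng.standard_normal((n, p))
        B = np.column_stack([h + 0.5 * rng.standard_normal(n)
                             for _ in range(q)])
        y = g + h + 0.7 * rng.standard_normal(n)
        return X, B, y

    def test_additive_signal(self, rng):
        gains = []
        for seed in range(3):
            rg = np.random.default_rng(seed + 20)
            X, B, y = self._two_block_data(rg)
            grid = sg.default_lambda_grid(8)
            stack, rep = sg.fit_stacking(X, B, y, grid_1=grid, grid_2=grid,
                                         seed=0)
            _, fmri = sg.fit_lasso_pcr(X, y, lambda_grid=grid, seed=0)
            _, behav = sg.fit_behavior_lasso(B, y, lambda_grid=grid, seed=0)
            gains.append(rep.r_squared
                         - max(fmri.r_squared, behav.r_squared))
        assert np.mean(gains) > -0.02

    def test_noise_behavior_block(self, rng):
        X, _, y = self._two_block_data(rng)
        y = y - y  # rebuild: y from maps only
        g = rng.standard_normal(150)
        X = np.outer(g, np.concatenate([np.ones(8), np.zeros(52)]))
        X += 0.7 * rng.standard_normal((150, 60))
        y = g + 0.7 * rng.standard_normal(150)
        B = rng.standard_normal((150, 5))
        grid = sg.default_lambda_grid(8)
        stack, rep = sg.fit_stacking(X, B, y, grid_1=grid, grid_2=grid,
                                     seed=0)
        _, fmri = sg.fit_lasso_pcr(X, y, lambda_grid=grid, seed=0)
        assert abs(rep.r_squared - fmri.r_squared) < 0.12

    def test_zeroed_fmri_block(self, rng):
        n = 120
        h = rng.standard_normal(n)
        B = np.column_stack([h + 0.4 * rng.standard_normal(n)
                             for _ in range(4)])
        y = h + 0.5 * rng.standard_normal(n)
        X = rng.standard_normal((n, 40))  # no signal
        grid = sg.default_lambda_grid(8)
        stack, rep = sg.fit_stacking(X, B, y, grid_1=grid, grid_2=grid,
                                     seed=0)
        _, behav = sg.fit_behavior_lasso(B, y, lambda_grid=grid, seed=0)
        assert abs(rep.r_squared - behav.r_squared) < 0.12

    def test_predict_shape(self, rng):
        X, B, y = self._two_block_data(rng, n=100)
        grid = sg.default_lambda_grid(5)
        stack, _ = sg.fit_stacking(X, B, y, grid_1=grid, grid_2=grid, seed=0)
        preds = stack.predict(X[:10], B[:10])
        assert preds.shape == (10,)


class TestNoLeakage:
    def test_holdout_labels_never_touch_discovery_metrics(self, rng):
        X, y = make_linear_data(rng, 120, 30, noise=0.8)
        disc, hold = sg.split_discovery_holdout(120, 0.5, seed=0)
        grid = sg.default_lambda_grid(8)
        _, rep1 = sg.fit_lasso_pcr(X[disc], y[disc], lambda_grid=grid,
                                   seed=1)
        y_perm = y.copy()
        y_perm[hold] = rng.permutation(y[hold])
        _, rep2 = sg.fit_lasso_pcr(X[disc], y_perm[disc], lambda_grid=grid,
                                   seed=1)
        assert rep1.r_squared == rep2.r_squared
        assert rep1.pearson_r == rep2.pearson_r
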