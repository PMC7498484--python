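import numpy as np
import pytest

from neurocurve import (CovariateTable, GLMSpec, GAMSpec, SVRSpec,
                        SmootherSpec, build_contrast, eval_curves, fit_gam,
                        fit_glm, fit_svr, fit_two_stage,
                        fit_two_stage_chunked, grid_search_svr,
                        preprocess_covariates, predict, split_design)


class TestGLM:
    def test_exact_line_interpolation(self):
        x = np.linspace(0, 1, 10)
        y = 1.0 + 2.0 * x
        fit = fit_glm(x[:, None], y, degrees=1)
        np.testing.assert_allclose(fit.coefs.ravel(), [1.0, 2.0], atol=1e-10)
        np.testing.assert_allclose(fit.fitted.ravel(), y, atol=1e-10)

    def test_exact_quadratic(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        fit = fit_glm(x[:, None], x ** 2, degrees=2)
        np.testing.assert_allclose(fit.coefs.ravel(), [0.0, 0.0, 1.0],
                                   atol=1e-10)

    def test_matches_normal_equations(self, rng):
        X = rng.normal(size=(50, 3))
        Y = rng.normal(size=(50, 4))
        fit = fit_glm(X, Y, degrees=1)
        B = np.hstack([np.ones((50, 1)), X])
        beta = np.linalg.solve(B.T @ B, B.T @ Y)
        np.testing.assert_allclose(fit.coefs, beta, atol=1e-8)

    def test_df_is_expanded_column_count(self):
        x = np.linspace(0, 1, 20)
        assert fit_glm(np.column_stack([x, x ** 3]), x, degrees=(2, 1)).df \
            == 3.0

    def test_rank_deficient_design_raises(self):
        x = np.linspace(0, 1, 10)
        with pytest.raises(np.linalg.LinAlgError):
            fit_glm(np.column_stack([x, 2 * x]), x, degrees=1)

    def test_mse_monotone_in_degree(self, rng):
        # nested hypothesis classes: higher degree never fits worse
        for _ in range(20):
            x = rng.uniform(-1, 1, 30)
            y = rng.normal(size=30)
            sses = [((fit_glm(x[:, None], y, degrees=d).fitted.ravel()
                      - y) ** 2).sum() for d in (1, 2, 3, 4)]
            assert all(a >= b - 1e-10 for a, b in zip(sses, sses[1:]))


class TestGAM:
    def test_linear_smoother_equals_glm(self, rng):
        X = rng.normal(size=(40, 2))
        y = rng.normal(size=40)
        gam = fit_gam(X, y, [SmootherSpec("linear"), SmootherSpec("linear")],
                      tol=1e-12)
        glm = fit_glm(X, y, degrees=1)
        np.testing.assert_allclose(gam.fitted, glm.fitted, atol=1e-8)

    def test_polynomial_smoother_equals_glm(self, rng):
        x = rng.uniform(-1, 1, 50)
        y = rng.normal(size=50)
        gam = fit_gam(x[:, None], y, SmootherSpec("polynomial", 3),
                      tol=1e-12)
        glm = fit_glm(x[:, None], y, degrees=3)
        np.testing.assert_allclose(gam.fitted, glm.fitted, atol=1e-8)

    def test_orthogonal_covariates_decouple(self, rng):
        # orthogonal centered columns: backfitting converges immediately
        # and components equal the marginal regressions
        A = np.hstack([np.ones((30, 1)), rng.normal(size=(30, 2))])
        q, _ = np.linalg.qr(A)
        X = q[:, 1:3]   # mutually orthogonal and mean-zero
        y = rng.normal(size=30)
        gam = fit_gam(X, y, [SmootherSpec("linear")] * 2, tol=1e-10)
        for j in range(2):
            xj = X[:, j]
            beta = (xj @ (y - y.mean())) / (xj @ xj)
            comp = gam.component(j, xj)[:, 0]
            np.testing.assert_allclose(comp, beta * xj - (beta * xj).mean(),
                                       atol=1e-8)

    def test_bspline_beats_linear_on_sine(self, rng):
        x = rng.uniform(0, 1, 100)
        z = rng.normal(size=100)
        y = np.sin(2 * np.pi * x) + 0.5 * z
        gam = fit_gam(np.column_stack([x, z]),
                      y, [SmootherSpec("bspline", 8), SmootherSpec("linear")])
        glm = fit_glm(np.column_stack([x, z]), y, degrees=1)
        sse_gam = ((gam.fitted.ravel() - y) ** 2).sum()
        sse_glm = ((glm.fitted.ravel() - y) ** 2).sum()
        assert sse_gam < sse_glm
        assert gam.df == 9.0

    def test_single_smoother_matches_basis_least_squares(self, rng):
        # one-covariate GAM reduces to a direct basis regression
        from patsy import dmatrix

        x = np.sort(rng.uniform(0, 1, 60))
        y = np.sin(2 * np.pi * x) + rng.normal(0, 0.1, 60)
        gam = fit_gam(x[:, None], y, SmootherSpec("bspline", 6), tol=1e-12)
        B = np.asarray(dmatrix("bs(x, df=6) - 1", {"x": x}))
        Bc = np.hstack([np.ones((60, 1)), B])
        beta = np.linalg.lstsq(Bc, y, rcond=None)[0]
        np.testing.assert_allclose(gam.fitted.ravel(), Bc @ beta, atol=1e-6)

    def test_backfitting_fixed_point(self, rng):
        # post-convergence each component equals its smoother applied to
        # the partial residual
        X = rng.normal(size=(50, 2))
        X[:, 1] += 0.5 * X[:, 0]
        y = rng.normal(size=50)
        gam = fit_gam(X, y, [SmootherSpec("linear")] * 2, tol=1e-12)
        comps = [gam.component(j, X[:, j])[:, 0] for j in range(2)]
        for j in range(2):
            partial = y - gam.alpha[0] - sum(c for k, c in enumerate(comps)
                                             if k != j)
            s = gam.smoothers[j]
            refit = s.B @ s.fit_coefs(partial)
            refit -= refit.mean()
            np.testing.assert_allclose(comps[j], refit, atol=1e-8)

    def test_nonconvergence_warns(self, rng):
        X = rng.normal(size=(30, 2))
        X[:, 1] = X[:, 0] + 1e-6 * X[:, 1]   # near-collinear: slow backfit
        y = rng.normal(size=30)
        with pytest.warns(UserWarning, match="converge"):
            fit_gam(X, y, [SmootherSpec("linear")] * 2, max_iter=2,
                    tol=1e-14)

    def test_spline_needs_enough_distinct_values(self):
        x = np.repeat([0.0, 1.0, 2.0], 5)
        with pytest.raises(ValueError, match="distinct"):
            fit_gam(x[:, None], np.arange(15.0), SmootherSpec("bspline", 5))


class TestSVR:
    def test_wide_tube_gives_flat_fit(self, rng):
        x = np.linspace(0, 1, 30)
        y = 3.0 + rng.normal(0, 0.05, 30)
        fit = fit_svr(x[:, None], y, eps=10.0, C=1.0)
        assert np.ptp(fit.fitted) < 1e-8
        assert np.abs(fit.betas).max() == 0.0

    def test_rbf_fits_noiseless_sine(self):
        x = np.linspace(0, 2 * np.pi, 60)
        y = np.sin(x)
        fit = fit_svr(x[:, None], y, kernel="rbf", eps=0.01, C=100.0,
                      gamma=1.0)
        assert ((fit.fitted.ravel() - y) ** 2).mean() < 0.01

    def test_linear_kernel_on_linear_data(self):
        x = np.linspace(0, 1, 25)
        y = 2.0 * x + 0.5
        fit = fit_svr(x[:, None], y, kernel="polynomial", eps=0.01, C=100.0,
                      gamma=1.0, degree=1)
        assert np.abs(fit.fitted.ravel() - y).max() < 0.011

    def test_predict_matches_sklearn(self, rng):
        # the stored kernel expansion reproduces sklearn's predictions
        from sklearn.svm import SVR

        x = rng.uniform(0, 2, 40)[:, None]
        y = rng.normal(size=40)
        fit = fit_svr(x, y, kernel="rbf", eps=0.1, C=5.0, gamma=2.0)
        ref = SVR(kernel="rbf", C=5.0, epsilon=0.1, gamma=2.0).fit(
            x, y)
        grid = np.linspace(0, 2, 17)[:, None]
        np.testing.assert_allclose(fit.predict(grid).ravel(),
                                   ref.predict(grid), atol=1e-8)

    def test_degenerate_design_constant_model(self):
        X = np.ones((10, 1))
        y = np.arange(10.0)
        fit = fit_svr(X, y, eps=0.1, C=1.0)
        assert fit.df == 1.0
        np.testing.assert_allclose(fit.fitted.ravel(), y.mean())

    def test_marginal_support_vector_df(self, rng):
        x = rng.uniform(0, 2 * np.pi, 50)[:, None]
        y = np.sin(x).ravel() + rng.normal(0, 0.2, 50)
        fit = fit_svr(x, y, eps=0.05, C=1.0)
        a = np.abs(fit.betas[:, 0])
        expected = ((a > 1e-10) & (a < 1.0 - 1e-10)).sum()
        assert fit.df == max(expected, 1)


class TestTwoStage:
    def test_empty_correctors_center_only(self, rng):
        x = rng.uniform(0, 2, 30)
        y = 2.0 + x + rng.normal(0, 0.1, 30)
        table = CovariateTable(x[:, None].repeat(2, axis=1) *
                               [1.0, 0.0] + [[0.0, 1.0]] * 30, ["p", "one"])
        # direct construction: predictor-only split
        from neurocurve.design import DesignSplit

        split = DesignSplit(XC=np.empty((30, 0)), XP=x[:, None],
                            df_C=0.0, df_P=1.0)
        model = fit_two_stage(y, split, None, GLMSpec(degrees=1))
        np.testing.assert_allclose(model.corrector_fitted.ravel(), y.mean())
        assert model.df_correctors == 1.0

    def test_matches_joint_fit_when_orthogonal(self, rng):
        t = CovariateTable(rng.normal(size=(40, 3)), ["a", "b", "p"])
        t = preprocess_covariates(t, "orthogonalize", demean=True)
        split = split_design(t, build_contrast(np.array([[0.], [0.], [1.]])))
        Y = rng.normal(size=(40, 3))
        model = fit_two_stage(Y, split, GLMSpec(1), GLMSpec(1))
        joint = np.hstack([np.ones((40, 1)), split.XC, split.XP])
        beta = np.linalg.lstsq(joint, Y, rcond=None)[0]
        np.testing.assert_allclose(model.fitted, joint @ beta, atol=1e-8)

    def test_corrector_residuals_orthogonal_to_correctors(self, small_phantom,
                                                          phantom_split):
        model = fit_two_stage(small_phantom.data[:, :50], phantom_split,
                              GLMSpec(degrees=(1, 2)), GLMSpec(degrees=2))
        resid = small_phantom.data[:, :50] - model.corrector_fitted
        for j in range(phantom_split.XC.shape[1]):
            xc = phantom_split.XC[:, j] - phantom_split.XC[:, j].mean()
            r = resid - resid.mean(axis=0)
            corr = np.abs(xc @ r) / (np.linalg.norm(xc)
                                     * np.linalg.norm(r, axis=0))
            assert corr.max() < 1e-6

    def test_gam_predictor_on_phantom(self, small_phantom, phantom_split):
        cols = np.flatnonzero(small_phantom.region_of_voxel == 2)[:5]
        model = fit_two_stage(
            small_phantom.data[:, cols], phantom_split,
            GLMSpec(degrees=(1, 2)),
            GAMSpec(smoothers=(SmootherSpec("bspline", 5),)))
        assert model.predictor.converged.all()
        assert model.df_predictors == 5.0

    def test_chunked_fit_bit_identical(self, rng):
        X = rng.normal(size=(30, 3))
        t = CovariateTable(X, ["a", "b", "p"])
        split = split_design(t, build_contrast(np.array([[0.], [0.], [1.]])))
        Y = rng.normal(size=(30, 23))
        full = fit_two_stage_chunked(Y, split, GLMSpec(1), GLMSpec(2), None)
        for chunk in (1, 7, 23):
            part = fit_two_stage_chunked(Y, split, GLMSpec(1), GLMSpec(2),
                                         chunk)
            assert np.array_equal(part.fitted, full.fitted)
            assert np.array_equal(part.predictor.coefs, full.predictor.coefs)


class TestPredictAndCurves:
    def test_predict_on_training_design_matches_fitted(self, rng):
        t = CovariateTable(rng.normal(size=(25, 2)), ["a", "p"])
        split = split_design(t, build_contrast(np.array([[0.], [1.]])))
        Y = rng.normal(size=(25, 4))
        model = fit_two_stage(Y, split, GLMSpec(1), GLMSpec(2))
        np.testing.assert_array_equal(predict(model), model.fitted)

    def test_glm_curve_is_the_fitted_line(self, rng):
        x = np.linspace(0, 1, 20)
        y = 0.5 + 2.0 * x
        from neurocurve.design import DesignSplit

        split = DesignSplit(XC=np.empty((20, 0)), XP=x[:, None],
                            df_C=0.0, df_P=1.0)
        model = fit_two_stage(y, split, None, GLMSpec(1))
        cs = eval_curves(model, T=5)
        np.testing.assert_allclose(cs.grid, np.linspace(0, 1, 5))
        beta = model.predictor.coefs[0, 0]
        np.testing.assert_allclose(cs.curves[0], beta * cs.grid, atol=1e-10)

    def test_gam_curve_sums_components(self, rng):
        x = rng.uniform(0, 2, 60)
        y = np.sin(np.pi * x) + rng.normal(0, 0.1, 60)
        from neurocurve.design import DesignSplit

        split = DesignSplit(XC=np.empty((60, 0)), XP=x[:, None],
                            df_C=0.0, df_P=5.0)
        model = fit_two_stage(y, split, None,
                              GAMSpec(smoothers=(SmootherSpec("bspline",
                                                              5),)))
        cs = eval_curves(model, T=50)
        direct = (model.predictor.alpha
                  + model.predictor.component(0, cs.grid).T)
        np.testing.assert_allclose(cs.curves, direct, atol=1e-10)

    def test_extrapolation_warns(self, rng):
        x = np.linspace(0, 1, 20)
        from neurocurve.design import DesignSplit

        split = DesignSplit(XC=np.empty((20, 0)), XP=x[:, None],
                            df_C=0.0, df_P=1.0)
        model = fit_two_stage(x, split, None, GLMSpec(1))
        with pytest.warns(UserWarning, match="extrapolat"):
            predict(model, XP_new=np.array([[2.0]]))

    def test_curve_grid_minimum(self, rng):
        x = np.linspace(0, 1, 20)
        from neurocurve.design import DesignSplit

        split = DesignSplit(XC=np.empty((20, 0)), XP=x[:, None],
                            df_C=0.0, df_P=1.0)
        model = fit_two_stage(x, split, None, GLMSpec(1))
        with pytest.raises(ValueError, match="T >= 5"):
            eval_curves(model, T=3)


class TestGridSearch:
    @staticmethod
    def _toy(rng, N=6):
        x = np.linspace(0, 2 * np.pi, 40)
        Y = np.sin(x)[:, None] + rng.normal(0, 0.1, (40, N))
        from neurocurve.design import DesignSplit

        split = DesignSplit(XC=np.empty((40, 0)), XP=x[:, None],
                            df_C=0.0, df_P=1.0)
        return Y, split

    def test_single_combination_returned(self, rng):
        Y, split = self._toy(rng)
        spec = grid_search_svr(Y, split, {"C": [3.0]}, H=1, subset_size=6)
        assert spec.C == 3.0

    def test_dominant_combination_wins(self, rng):
        # gamma ~ 1 fits a sine; gamma absurdly small cannot
        Y, split = self._toy(rng)
        spec = grid_search_svr(Y, split, {"gamma": [1e-6, 1.0]},
                               subset_size=3, iterations=3, seed=1,
                               base_spec=None)
        assert spec.gamma == 1.0

    def test_matches_exhaustive_oracle(self, rng):
        Y, split = self._toy(rng)
        Cs, gammas = [0.1, 1.0, 10.0], [0.1, 1.0, 10.0]
        spec = grid_search_svr(Y, split, {"C": Cs, "gamma": gammas},
                               subset_size=Y.shape[1], metric="mse",
                               iterations=1, seed=0)
        # oracle: exhaustive weighted-SSE evaluation of the 3x3 grid
        sigma = Y.var(axis=0)
        best, best_t = None, np.inf
        for C in Cs:
            for g in gammas:
                model = fit_two_stage(Y, split, None,
                                      SVRSpec(C=C, gamma=g))
                ss = ((Y - model.fitted) ** 2).sum(axis=0)
                t = (ss / sigma).sum()
                if t < best_t - 1e-12:
                    best, best_t = (C, g), t
        assert (spec.C, spec.gamma) == best

    @pytest.mark.parametrize("sampling", ["deterministic-linear",
                                          "deterministic-log", "random"])
    def test_sampled_ranges_stay_in_bounds(self, rng, sampling):
        Y, split = self._toy(rng)
        spec = grid_search_svr(Y, split,
                               {"C": (0.1, 10.0), "gamma": (0.1, 3.0)},
                               sampling=sampling, H=9, subset_size=6,
                               seed=3)
        assert 0.1 <= spec.C <= 10.0
        assert 0.1 <= spec.gamma <= 3.0

    def test_no_eligible_observations_raises(self, rng):
        Y = np.ones((20, 4))
        from neurocurve.design import DesignSplit

        split = DesignSplit(XC=np.empty((20, 0)),
                            XP=np.linspace(0, 1, 20)[:, None],
                            df_C=0.0, df_P=1.0)
        with pytest.raises(ValueError, match="variance"):
            grid_search_svr(Y, split, {"C": [1.0, 2.0]}, sigma_min=0.5)
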