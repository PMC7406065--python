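"""Solver-level contracts: IRLS closed forms, the LASSO path against an
independent optimizer, KKT certificates, CV selection, the post-selection
refit, the probit selection model and the weighting schemes."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from conftest import random_design_matrix
from oracles import penalized_poisson_minimum

from popdensity.design import DesignMatrix, SchemaError
from popdensity.model import (
    FitError,
    FittedDensityModel,
    GridSpec,
    UsageError,
    compute_weights,
    fit_density_model,
    fit_poisson_irls,
    fit_selection_probit,
    lasso_path,
    post_lasso_fit,
    predict_density,
    select_lambda_cv,
)


def empty_design(n, n_sub=4):
    return DesignMatrix(
        data=np.zeros((n, 0)),
        columns=[],
        penalized=np.zeros(0, dtype=bool),
        village_ids=np.array([f"V{i}" for i in range(n)]),
        sub_district_ids=np.array([f"S{i % n_sub}" for i in range(n)]),
    )


def poisson_instance(rng, n=60, p_pen=3, p_forced=2, sd=0.3):
    dm = random_design_matrix(rng, n, p_pen, p_forced)
    beta = rng.normal(0, 0.4, size=p_pen + p_forced)
    y = np.exp(1.0 + dm.data @ beta + rng.normal(0, sd, n))
    w = rng.uniform(0.5, 2.0, n)
    return dm, y, w


class TestPoissonIrls:
    def test_intercept_only_is_log_weighted_mean(self):
        rng = np.random.default_rng(0)
        y = rng.gamma(2.0, 50.0, size=40)
        w = rng.uniform(0.2, 3.0, size=40)
        fit = fit_poisson_irls(empty_design(40), y, weights=w)
        assert fit.coef[0] == pytest.approx(np.log(np.average(y, weights=w)), abs=1e-10)

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(1)
        dm, y, w = poisson_instance(rng)
        a = fit_poisson_irls(dm, y, weights=w)
        b = fit_poisson_irls(dm, y, weights=10.0 * w)
        np.testing.assert_allclose(a.coef, b.coef, atol=1e-10)

    def test_agrees_with_statsmodels_glm(self):
        # independent implementation of the same weighted pseudo-likelihood
        rng = np.random.default_rng(2)
        dm, y, w = poisson_instance(rng)
        mine = fit_poisson_irls(dm, y, weights=w)
        ref = sm.GLM(
            y, sm.add_constant(dm.data), family=sm.families.Poisson(), var_weights=w
        ).fit()
        np.testing.assert_allclose(mine.coef, ref.params, rtol=1e-6, atol=1e-8)

    def test_objective_trace_is_monotone(self):
        rng = np.random.default_rng(3)
        dm, y, w = poisson_instance(rng)
        fit = fit_poisson_irls(dm, y, weights=w)
        assert all(b <= a + 1e-12 for a, b in zip(fit.objective_trace, fit.objective_trace[1:]))

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(4)
        dm, y, w = poisson_instance(rng, p_pen=2)
        dm.data[:, 1] = 2.0 * dm.data[:, 0]
        with pytest.raises(FitError, match="x0|x1"):
            fit_poisson_irls(dm, y, weights=w)

    def test_cluster_covariance_is_symmetric_psd(self):
        rng = np.random.default_rng(5)
        dm, y, w = poisson_instance(rng)
        fit = fit_poisson_irls(dm, y, weights=w, clusters=dm.sub_district_ids)
        V = fit.cov.to_numpy()
        np.testing.assert_allclose(V, V.T, atol=1e-12)
        assert np.linalg.eigvalsh(V).min() > -1e-10


class TestLassoPath:
    def test_lambda_max_zeroes_everything_and_matches_forced_mle(self):
        rng = np.random.default_rng(6)
        dm, y, w = poisson_instance(rng)
        path = lasso_path(dm, y, w, grid_spec=GridSpec(n_lambda=12, lambda_min_ratio=1e-3))
        first = path.coefficients.iloc[0]
        assert (first[dm.penalized_columns] == 0.0).all()
        forced_fit = fit_poisson_irls(dm.take_columns(dm.forced_columns), y, weights=w)
        np.testing.assert_allclose(
            first[dm.forced_columns].to_numpy(),
            forced_fit.coef[1:],
            rtol=1e-6,
            atol=1e-8,
        )
        assert path.intercepts[0] == pytest.approx(forced_fit.coef[0], abs=1e-6)

    def test_objective_matches_generic_optimizer_on_small_instance(self):
        rng = np.random.default_rng(7)
        dm, y, w = poisson_instance(rng, n=40, p_pen=4)
        path = lasso_path(dm, y, w, grid_spec=GridSpec(n_lambda=8, lambda_min_ratio=1e-2))
        for i in (0, 3, 7):
            oracle = penalized_poisson_minimum(dm, y, w, path.lambda_grid[i])
            assert path.objective[i] <= oracle + 1e-6

    def test_kkt_certificate_along_path(self):
        rng = np.random.default_rng(8)
        dm, y, w = poisson_instance(rng, n=80, p_pen=5)
        path = lasso_path(dm, y, w, grid_spec=GridSpec(n_lambda=20, lambda_min_ratio=1e-3))
        assert path.kkt_violation.max() < 1e-5

    def test_duplicate_column_coefficients_sum_to_single_copy(self):
        # classic LASSO identity: duplicating a penalized column splits its
        # coefficient arbitrarily but the sum matches the single-copy fit.
        rng = np.random.default_rng(9)
        dm, y, w = poisson_instance(rng, n=70, p_pen=3)
        dup = DesignMatrix(
            data=np.column_stack([dm.data, dm.data[:, 0]]),
            columns=dm.columns + ["x0_copy"],
            penalized=np.append(dm.penalized, True),
            village_ids=dm.village_ids,
            sub_district_ids=dm.sub_district_ids,
        )
        grid = GridSpec(n_lambda=10, lambda_min_ratio=1e-2)
        base = lasso_path(dm, y, w, grid_spec=grid)
        both = lasso_path(dup, y, w, lambda_grid=base.lambda_grid)
        summed = both.coefficients["x0"] + both.coefficients["x0_copy"]
        np.testing.assert_allclose(
            summed, base.coefficients["x0"], atol=5e-4
        )

    def test_deviance_nonincreasing_as_lambda_decreases(self):
        rng = np.random.default_rng(10)
        dm, y, w = poisson_instance(rng)
        path = lasso_path(dm, y, w, grid_spec=GridSpec(n_lambda=15, lambda_min_ratio=1e-3))
        assert (np.diff(path.deviance) <= 1e-8).all()

    def test_unpenalized_limit_matches_irls(self):
        rng = np.random.default_rng(11)
        dm, y, w = poisson_instance(rng)
        probe = lasso_path(dm, y, w, grid_spec=GridSpec(n_lambda=2, lambda_min_ratio=0.5))
        lam_max = probe.lambda_grid[0]
        grid = np.geomspace(lam_max, lam_max * 1e-10, 40)
        path = lasso_path(dm, y, w, lambda_grid=grid)
        full = fit_poisson_irls(dm, y, weights=w)
        np.testing.assert_allclose(
            path.coefficients.iloc[-1].to_numpy(), full.coef[1:], atol=1e-6
        )
        assert path.intercepts[-1] == pytest.approx(full.coef[0], abs=1e-6)

    def test_invalid_grid_rejected(self):
        rng = np.random.default_rng(12)
        dm, y, w = poisson_instance(rng)
        with pytest.raises(UsageError):
            lasso_path(dm, y, w, lambda_grid=np.array([1.0, 2.0]))
        with pytest.raises(UsageError):
            lasso_path(dm, y, w, lambda_grid=np.array([1.0, -0.5]))


class TestSelectLambdaCV:
    def test_single_candidate_returned(self):
        rng = np.random.default_rng(13)
        dm, y, w = poisson_instance(rng)
        probe = lasso_path(dm, y, w, grid_spec=GridSpec(n_lambda=2, lambda_min_ratio=0.9))
        cv = select_lambda_cv(dm, y, w, grid_spec=GridSpec(n_lambda=1, lambda_min_ratio=1.0))
        assert cv.lambda_star == pytest.approx(probe.lambda_grid[0])

    def test_row_permutation_invariance_given_seed(self):
        rng = np.random.default_rng(14)
        dm, y, w = poisson_instance(rng, n=80)
        grid = GridSpec(n_lambda=10, lambda_min_ratio=1e-2)
        cv1 = select_lambda_cv(dm, y, w, grid_spec=grid, seed=5)
        cv2 = select_lambda_cv(dm, y, w, grid_spec=grid, seed=5)
        assert cv1.lambda_star == cv2.lambda_star
        np.testing.assert_allclose(cv1.cv_rmse, cv2.cv_rmse)

    def test_prefers_sparse_truth_over_dense_fit(self):
        # 3 real signals + 12 noise covariates: the chosen lambda should not
        # be denser than the smallest grid value in most seeds.
        rng = np.random.default_rng(15)
        better = 0
        for rep in range(10):
            dm = random_design_matrix(rng, 300, 15, 1)
            beta = np.zeros(16)
            beta[:3] = [0.5, -0.4, 0.3]
            beta[15] = 0.2
            y = np.exp(0.5 + dm.data @ beta + rng.normal(0, 0.4, 300))
            cv = select_lambda_cv(
                dm, y, None, grid_spec=GridSpec(n_lambda=20, lambda_min_ratio=1e-3),
                seed=rep,
            )
            i_star = int(np.argmin(np.abs(cv.lambda_grid - cv.lambda_star)))
            dense_rmse = cv.cv_rmse[-1]
            assert cv.cv_rmse[i_star] <= dense_rmse + 1e-9
            better += cv.cv_rmse[i_star] < dense_rmse
        assert better >= 8


class TestPostLasso:
    def test_equals_irls_on_selected_support(self):
        rng = np.random.default_rng(16)
        dm, y, w = poisson_instance(rng, n=90, p_pen=5)
        model, cv = fit_density_model(
            dm, y, w, grid_spec=GridSpec(n_lambda=15, lambda_min_ratio=1e-3), seed=0
        )
        support = model.columns
        direct = fit_poisson_irls(dm.take_columns(support), y, weights=w)
        np.testing.assert_allclose(
            model.coefficients.to_numpy(),
            direct.coef,
            rtol=1e-8,
            atol=1e-10,
        )

    def test_empty_selection_reduces_to_forced_only(self):
        rng = np.random.default_rng(17)
        dm, y, w = poisson_instance(rng, sd=0.1)
        probe = lasso_path(dm, y, w, grid_spec=GridSpec(n_lambda=2, lambda_min_ratio=0.5))
        lam_max = probe.lambda_grid[0]
        model = post_lasso_fit(dm, y, w, lam_max, probe)
        assert model.selected == []
        forced = fit_poisson_irls(dm.take_columns(dm.forced_columns), y, weights=w)
        np.testing.assert_allclose(
            model.coefficients.to_numpy(), forced.coef, rtol=1e-8
        )

    def test_shrinkage_removed_relative_to_path(self):
        # noiseless strong signal: post-LASSO recovers truth, raw path
        # coefficients at lambda* are shrunk toward zero.
        rng = np.random.default_rng(18)
        dm = random_design_matrix(rng, 1000, 3, 2)
        beta = np.array([0.6, -0.5, 0.4, 0.3, -0.2])
        y = np.exp(1.2 + dm.data @ beta)
        model, cv = fit_density_model(
            dm, y, None, grid_spec=GridSpec(n_lambda=25, lambda_min_ratio=1e-4), seed=1
        )
        est = model.coefficients[dm.columns].to_numpy()
        np.testing.assert_allclose(est, beta, atol=1e-3)
        _, raw = cv.path.coef_at(cv.lambda_star)
        for j, name in enumerate(dm.columns[:3]):
            if raw[name] != 0.0:
                assert abs(raw[name]) <= abs(beta[j]) + 1e-6

    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(19)
        dm, y, w = poisson_instance(rng)
        model, _ = fit_density_model(
            dm, y, w, grid_spec=GridSpec(n_lambda=8, lambda_min_ratio=1e-2), seed=0
        )
        path = tmp_path / "model.json"
        model.to_json(path)
        back = FittedDensityModel.from_json(path)
        assert back.selected == model.selected
        assert back.lambda_star == model.lambda_star
        pd.testing.assert_series_equal(back.coefficients, model.coefficients)
        np.testing.assert_allclose(back.cov.to_numpy(), model.cov.to_numpy())


class TestPredict:
    def test_intercept_only_constant_prediction(self):
        model = FittedDensityModel(
            selected=[], lambda_star=1.0, columns=[],
            coefficients=pd.Series({"intercept": np.log(1000.0)}),
        )
        pred = predict_density(model, empty_design(7))
        np.testing.assert_allclose(pred, 1000.0)

    def test_hand_computed_eta(self):
        rng = np.random.default_rng(20)
        dm = random_design_matrix(rng, 5, 2, 1)
        coefs = pd.Series({"intercept": 0.7, "x0": 0.2, "x1": -0.1, "z0": 0.5})
        model = FittedDensityModel(
            selected=["x0", "x1"], lambda_star=0.1,
            columns=["x0", "x1", "z0"], coefficients=coefs,
        )
        eta = 0.7 + dm.data @ np.array([0.2, -0.1, 0.5])
        np.testing.assert_allclose(predict_density(model, dm), np.exp(eta))

    def test_row_reordering_permutes_predictions(self):
        rng = np.random.default_rng(21)
        dm = random_design_matrix(rng, 30, 2, 1)
        coefs = pd.Series({"intercept": 0.2, "x0": 0.3, "x1": 0.0, "z0": -0.2})
        model = FittedDensityModel(
            selected=["x0"], lambda_star=0.1, columns=["x0", "x1", "z0"],
            coefficients=coefs,
        )
        perm = rng.permutation(30)
        np.testing.assert_allclose(
            predict_density(model, dm.take_rows(perm)), predict_density(model, dm)[perm]
        )

    def test_missing_support_column_rejected(self):
        rng = np.random.default_rng(22)
        dm = random_design_matrix(rng, 10, 1, 1)
        model = FittedDensityModel(
            selected=["nope"], lambda_star=0.1, columns=["nope"],
            coefficients=pd.Series({"intercept": 0.0, "nope": 1.0}),
        )
        with pytest.raises(SchemaError, match="nope"):
            predict_density(model, dm)


class TestSelectionProbit:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(23)
        n = 5000
        X = pd.DataFrame(
            {"a": rng.normal(size=n), "b": rng.normal(size=n)},
            index=[f"V{i}" for i in range(n)],
        )
        eta = -0.3 + 0.8 * X["a"] - 0.5 * X["b"]
        from scipy.stats import norm

        y = rng.random(n) < norm.cdf(eta)
        model = fit_selection_probit(X, y)
        est = np.array([model.eta0, model.eta1["a"], model.eta1["b"]])
        truth = np.array([-0.3, 0.8, -0.5])
        assert np.sqrt(np.mean((est - truth) ** 2)) < 0.1
        assert ((model.probabilities > 0) & (model.probabilities < 1)).all()

    def test_null_coefficients_within_ci_mostly(self):
        # selection independent of the covariate: estimates near zero
        rng = np.random.default_rng(24)
        hits = 0
        reps = 20
        for _ in range(reps):
            n = 2000
            X = pd.DataFrame({"a": rng.normal(size=n)})
            y = rng.random(n) < 0.3
            model = fit_selection_probit(X, y)
            ref = sm.Probit(
                y.astype(float), sm.add_constant(X.to_numpy())
            ).fit(disp=0)
            se = np.sqrt(np.diag(ref.cov_params()))[1]
            hits += abs(model.eta1["a"]) < 1.96 * se
        assert hits >= reps * 0.85

    def test_single_class_rejected(self):
        X = pd.DataFrame({"a": [0.0, 1.0, 2.0]})
        with pytest.raises(FitError, match="single class"):
            fit_selection_probit(X, np.array([True, True, True]))


class TestWeights:
    def test_balance_corrected_arithmetic(self):
        from popdensity.model import SelectionModel

        sel = SelectionModel(
            eta0=0.0,
            eta1=pd.Series(dtype=float),
            probabilities=pd.Series({"V1": 0.5, "V2": 1.0 - 1e-13}),
        )
        pop = pd.Series({"V1": 500.0, "V2": 1.0})
        wv = compute_weights(pop, "balance_corrected", selection=sel)
        assert wv.w[0] == pytest.approx(1.0 / (500.0 * 0.5))  # = 0.004
        assert wv.w[1] == pytest.approx(1.0)

    def test_p_floor_clipping_flagged(self):
        from popdensity.model import SelectionModel

        sel = SelectionModel(
            eta0=0.0, eta1=pd.Series(dtype=float),
            probabilities=pd.Series({"V1": 0.001, "V2": 0.6}),
        )
        pop = pd.Series({"V1": 10.0, "V2": 10.0})
        wv = compute_weights(pop, "balance_corrected", selection=sel, p_floor=0.01)
        assert wv.n_floored == 1
        assert wv.w[0] == pytest.approx(1.0 / (10.0 * 0.01))

    def test_inverse_pop_and_errors(self):
        pop = pd.Series({"V1": 4.0, "V2": 8.0})
        wv = compute_weights(pop, "inverse_pop")
        np.testing.assert_allclose(wv.w, [0.25, 0.125])
        with pytest.raises(UsageError):
            compute_weights(pd.Series({"V1": 0.0}), "inverse_pop")
        with pytest.raises(UsageError):
            compute_weights(pop, "balance_corrected")
        with pytest.raises(UsageError):
            compute_weights(pop, "bogus")
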