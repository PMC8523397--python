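"""Elastic-net classifier: grids, objective, CV protocol, leakage checks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from tibrad.model import (
    CVProtocol,
    ModelSpec,
    build_design_matrix,
    build_grids,
    fit_elastic_net,
    grid_search_cv,
    objective,
    penalty,
)


def synthetic_problem(n=120, p=6, seed=0, effect=1.5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[:2] = (effect, -effect)
    eta = X @ beta - 0.5
    y = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(p)]), y.astype(int)


class TestGrids:
    def test_alpha_grid_19_values(self):
        alphas, _ = build_grids()
        assert len(alphas) == 19
        assert alphas[0] == pytest.approx(0.1)
        assert alphas[-1] == pytest.approx(1.0)

    def test_lambda_grid_17_values_endpoint_off_grid(self):
        _, lams = build_grids()
        assert len(lams) == 17
        assert lams[0] == pytest.approx(0.001)
        assert lams[-1] == pytest.approx(0.145)  # 0.15 is off-grid

    def test_degenerate_single_value(self):
        a, l = build_grids((0.5, 0.5, 0.1), (0.01, 0.01, 0.009))
        assert list(a) == [0.5] and list(l) == [0.01]

    def test_bad_bounds_rejected(self):
        with pytest.raises(ValueError):
            build_grids((1.0, 0.1, 0.05))


class TestPenalty:
    def test_zero_beta(self):
        assert penalty(np.zeros(4), 0.5, 0.1) == 0.0

    def test_lasso_hand_value(self):
        assert penalty(np.array([1.0, -2.0]), 1.0, 1.0) == pytest.approx(3.0)

    def test_ridge_hand_value(self):
        assert penalty(np.array([1.0, -2.0]), 0.0, 2.0) == pytest.approx(5.0)


class TestDesignMatrix:
    @pytest.fixture()
    def cohort_and_features(self):
        from tibrad.phantom import PhantomParams, generate_cohort

        cohort = generate_cohort(30, 0.3, PhantomParams(), seed=5)
        rng = np.random.default_rng(0)
        cols = {}
        for voi in ("SBM", "MidM", "TBM", "SBL", "MidL", "TBL"):
            for i in range(286):
                cols[f"{voi}_feat{i}"] = rng.normal(size=30)
        for i in range(17):
            cols[f"shape_s{i}"] = rng.normal(size=30)
        feats = pd.DataFrame(cols, index=cohort["subject_id"])
        return cohort, feats

    def test_covariate_mode_two_columns(self, cohort_and_features):
        cohort, feats = cohort_and_features
        X, y = build_design_matrix(cohort, feats, ModelSpec(mode="covariates"))
        assert list(X.columns) == ["age", "bmi"]
        assert y.sum() == 9

    def test_single_voi_image_mode_286_columns(self, cohort_and_features):
        cohort, feats = cohort_and_features
        X, _ = build_design_matrix(cohort, feats, ModelSpec(mode="image", voi_selection="SBM"))
        assert X.shape[1] == 286  # 3 orientation + 12 histogram + 271 texture

    def test_combined_is_image_plus_two(self, cohort_and_features):
        cohort, feats = cohort_and_features
        Xi, _ = build_design_matrix(cohort, feats, ModelSpec(mode="image", voi_selection="All"))
        Xc, _ = build_design_matrix(cohort, feats, ModelSpec(mode="combined", voi_selection="All"))
        assert Xc.shape[1] == Xi.shape[1] + 2
        assert Xi.shape[1] == 6 * 286 + 17  # shape included only for "All"

    def test_zero_variance_column_named(self, cohort_and_features):
        cohort, feats = cohort_and_features
        feats = feats.copy()
        feats["SBM_feat0"] = 1.0
        with pytest.raises(ValueError, match="SBM_feat0"):
            build_design_matrix(cohort, feats, ModelSpec(mode="image", voi_selection="SBM"))


class TestFitElasticNet:
    def test_huge_lambda_saturates_to_intercept_only(self):
        X, y = synthetic_problem()
        fit = fit_elastic_net(X, y, alpha=0.5, lam=50.0)
        assert np.abs(fit.coef).max() < 1e-6
        p_hat = y.mean()
        assert fit.intercept == pytest.approx(np.log(p_hat / (1 - p_hat)), abs=0.05)

    def test_tiny_lambda_matches_unpenalized_logistic(self):
        import statsmodels.api as sm

        X, y = synthetic_problem(n=200, p=2, seed=3)
        fit = fit_elastic_net(X, y, alpha=0.5, lam=1e-7, tol=1e-10)
        ref = sm.Logit(y, sm.add_constant(X.to_numpy())).fit(disp=0)
        assert fit.intercept == pytest.approx(ref.params[0], abs=1e-3)
        assert np.allclose(fit.coef.to_numpy(), ref.params[1:], atol=1e-3)

    def test_objective_not_worse_than_generic_optimizer(self):
        """Solver objective <= a derivative-free optimizer's, within 1e-6."""
        X, y = synthetic_problem(n=40, p=3, seed=1)
        alpha, lam = 0.5, 0.05
        fit = fit_elastic_net(X, y, alpha, lam, tol=1e-12, max_iter=100000)
        ours = objective(X.to_numpy(), y, fit.coef.to_numpy(), fit.intercept, alpha, lam)

        def f(w):
            return objective(X.to_numpy(), y, w[1:], w[0], alpha, lam)

        res = minimize(f, np.zeros(4), method="Powell", options={"xtol": 1e-10, "ftol": 1e-12})
        assert ours <= res.fun + 1e-6

    def test_objective_trace_never_increases(self):
        X, y = synthetic_problem(n=100, p=5, seed=9)
        fit = fit_elastic_net(X, y, alpha=0.7, lam=0.02, record_trace=True)
        trace = np.array(fit.objective_trace)
        assert (np.diff(trace) <= 1e-12).all()

    def test_single_class_rejected(self):
        X, _ = synthetic_problem()
        with pytest.raises(ValueError):
            fit_elastic_net(X, np.zeros(len(X), dtype=int), 0.5, 0.1)


class TestGridSearchCV:
    def test_single_grid_point_reduces_to_repeated_cv(self):
        X, y = synthetic_problem(n=100, p=4, seed=2)
        spec = ModelSpec(mode="image", voi_selection="SBM", alpha_grid=(0.5,), lambda_grid=(0.05,))
        fit = grid_search_cv(X, y, spec, CVProtocol(folds=5, repetitions=3, seed=1))
        assert len(fit.rep_roc_auc) == 3
        assert len(fit.cv_results) == 1
        assert fit.alpha == 0.5 and fit.lam == 0.05

    def test_informative_problem_beats_chance(self):
        X, y = synthetic_problem(n=150, p=5, seed=4, effect=2.0)
        spec = ModelSpec(alpha_grid=(0.5, 1.0), lambda_grid=(0.01, 0.05))
        fit = grid_search_cv(X, y, spec, CVProtocol(folds=5, repetitions=2, seed=2))
        assert np.mean(fit.rep_roc_auc) > 0.75

    def test_nonzero_count_nonincreasing_in_lambda_at_lasso(self):
        X, y = synthetic_problem(n=150, p=8, seed=5, effect=1.0)
        _, lams = build_grids()
        counts = []
        for lam in lams:
            fit = fit_elastic_net(X, y, alpha=1.0, lam=float(lam), tol=1e-9)
            counts.append(int((np.abs(fit.coef) > 1e-9).sum()))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_too_few_minority_subjects_rejected(self):
        X, y = synthetic_problem(n=30, p=3)
        y = np.zeros(30, dtype=int)
        y[:4] = 1
        spec = ModelSpec(alpha_grid=(0.5,), lambda_grid=(0.05,))
        with pytest.raises(ValueError, match="stratif"):
            grid_search_cv(X, y, spec, CVProtocol(folds=10, repetitions=1, seed=0))

    def test_standardization_uses_training_folds_only(self):
        """Corrupting held-out rows leaves that fold's scaler and fit unchanged."""
        X, y = synthetic_problem(n=60, p=3, seed=6)
        spec = ModelSpec(alpha_grid=(0.5,), lambda_grid=(0.05,))
        protocol = CVProtocol(folds=3, repetitions=1, seed=7)
        fit1 = grid_search_cv(X, y, spec, protocol, return_fold_details=True)
        d1 = fit1.fold_details

        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=7)
        splits = list(skf.split(np.zeros(60), y))
        test0 = splits[0][1]
        X2 = X.copy()
        X2.iloc[test0] = 999.0
        fit2 = grid_search_cv(X2, y, spec, protocol, return_fold_details=True)
        d2 = fit2.fold_details
        # fold 0 trains without the corrupted rows: identical scaler and coef
        assert np.allclose(d1[0]["scaler_mean"], d2[0]["scaler_mean"])
        assert np.allclose(d1[0]["coef"], d2[0]["coef"])
        # other folds train on corrupted rows: scalers must move
        assert not np.allclose(d1[1]["scaler_mean"], d2[1]["scaler_mean"])

    def test_deterministic_given_seed(self):
        X, y = synthetic_problem(n=80, p=4, seed=8)
        spec = ModelSpec(alpha_grid=(0.5,), lambda_grid=(0.05,))
        a = grid_search_cv(X, y, spec, CVProtocol(folds=4, repetitions=2, seed=3))
        b = grid_search_cv(X, y, spec, CVProtocol(folds=4, repetitions=2, seed=3))
        assert np.allclose(a.coef, b.coef)
        assert a.rep_roc_auc == b.rep_roc_auc
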