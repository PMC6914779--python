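import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from somanet import (
    adaptive_lasso,
    final_signature,
    jackknife_frequencies,
    normalize_pipeline,
    prepare_design,
    ridge_weights,
    run_selection,
)
from somanet.select import DesignMatrix
import somanet._solvers as solvers


def design_from(X, y, names=None):
    X = np.asarray(X, dtype=float)
    names = names or [f"A{j}" for j in range(X.shape[1])]
    return DesignMatrix(
        X=np.ascontiguousarray(X), y=np.asarray(y, dtype=float),
        analytes=list(names), sample_ids=[f"S{i}" for i in range(X.shape[0])],
        column_means=X.mean(axis=0), column_sds=X.std(axis=0),
    )


def toy_design(n=40, p=12, n_signal=2, seed=0, effect=1.5):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    eta = effect * X[:, :n_signal].sum(axis=1)
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    return design_from(X, y)


class TestSolver:
    def test_ridge_matches_direct_minimization(self):
        """Single-predictor ridge logistic agrees with a numerical-optimizer
        oracle on the penalized deviance to < 1e-6."""
        X = np.array([[-1.0], [-1.0], [1.0], [1.0]])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        lam = 1.0

        def objective(theta):
            b0, b = theta
            eta = b0 + X[:, 0] * b
            s = 2 * y - 1
            return np.mean(np.log1p(np.exp(-s * eta))) + 0.5 * lam * b * b

        beta, b0, ok = solvers.fit_penalized_logistic(X, y, l1=0.0, l2=lam, tol=1e-10)
        oracle = minimize(objective, [0.0, 0.0], method="BFGS",
                          options={"gtol": 1e-12}).x
        assert ok
        assert beta[0] == pytest.approx(oracle[1], abs=1e-6)

    def test_multivariate_ridge_matches_direct_minimization(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((25, 4))
        y = (rng.random(25) < 0.5).astype(float)
        lam = 0.3

        def objective(theta):
            eta = theta[0] + X @ theta[1:]
            s = 2 * y - 1
            return np.mean(np.log1p(np.exp(-s * eta))) + 0.5 * lam * np.sum(theta[1:] ** 2)

        beta, b0, _ = solvers.fit_penalized_logistic(X, y, l1=0.0, l2=lam, tol=1e-10)
        oracle = minimize(objective, np.zeros(5), method="BFGS", options={"gtol": 1e-12}).x
        assert b0 == pytest.approx(oracle[0], abs=1e-6)
        assert np.allclose(beta, oracle[1:], atol=1e-6)

    def test_lasso_matches_liblinear(self):
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(0)
        X = rng.standard_normal((60, 10))
        y = (rng.random(60) < 1 / (1 + np.exp(-X[:, 0]))).astype(float)
        lam = 0.05
        beta, b0, _ = solvers.fit_penalized_logistic(X, y, l1=lam, l2=0.0, tol=1e-10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = LogisticRegression(
                l1_ratio=1.0, C=1.0 / (lam * 60), solver="liblinear",
                intercept_scaling=1000.0, tol=1e-10, max_iter=10000, random_state=0,
            ).fit(X, y)
        assert np.allclose(beta, ref.coef_[0], atol=1e-3)
        assert (beta != 0).tolist() == (np.abs(ref.coef_[0]) > 1e-8).tolist()

    def test_loo_skip_equals_explicit_removal(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((20, 5))
        y = (rng.random(20) < 0.5).astype(float)
        l1 = np.full(5, 0.02)
        l2 = np.zeros(5)
        beta_skip = np.zeros(5)
        b0_skip, _ = solvers._cd_fit(X, y, l1, l2, beta_skip, 0.0,
                                     solvers.MAX_OUTER, solvers.MAX_INNER, 1e-10, 3)
        beta_del, b0_del, _ = solvers.fit_penalized_logistic(
            np.delete(X, 3, axis=0), np.delete(y, 3), l1, l2, tol=1e-10
        )
        assert b0_skip == pytest.approx(b0_del, abs=1e-6)
        assert np.allclose(beta_skip, beta_del, atol=1e-6)


class TestPrepareDesign:
    def test_standardization_contract(self, small_cohort):
        matrix, samples, _ = small_cohort
        normalized, _ = normalize_pipeline(matrix)
        design = prepare_design(
            normalized, list(normalized.assay_analytes), samples.loc[normalized.samples]
        )
        assert np.all(np.abs(design.X.mean(axis=0)) < 1e-10)
        assert np.all(np.abs(design.X.std(axis=0) - 1) < 1e-10)
        assert set(design.y) <= {0.0, 1.0}

    def test_constant_column_dropped(self, small_cohort):
        matrix, samples, _ = small_cohort
        m = matrix.copy()
        first = m.assay_analytes[0]
        m.values[first] = 123.0
        with pytest.warns(UserWarning, match="zero-variance"):
            design = prepare_design(m, list(m.assay_analytes), samples)
        assert first in design.dropped
        assert first not in design.analytes

    def test_column_order_invariance(self, small_cohort):
        matrix, samples, _ = small_cohort
        analytes = list(matrix.assay_analytes[:10])
        d1 = prepare_design(matrix, analytes, samples)
        d2 = prepare_design(matrix, analytes[::-1], samples)
        assert d1.analytes == d2.analytes
        assert np.array_equal(d1.X, d2.X)


class TestRidgeWeights:
    def test_zero_design_gives_capped_weights(self):
        design = design_from(np.zeros((12, 3)), [0, 1] * 6)
        lam, coefs, weights = ridge_weights(design, lambda_grid=[1.0, 0.1])
        assert np.allclose(coefs, 0.0)
        assert np.allclose(weights, solvers.WEIGHT_CAP)

    def test_heavy_penalty_shrinks_to_zero(self):
        design = toy_design()
        _, coefs, _ = ridge_weights(design, lambda_grid=[1e6])
        assert np.abs(coefs).max() < 1e-3

    def test_informative_predictors_get_smaller_weights(self):
        design = toy_design(n=80, p=10, n_signal=2, seed=5)
        _, _, weights = ridge_weights(design, lambda_grid=np.geomspace(10, 1e-3, 12))
        assert weights.iloc[:2].max() < weights.iloc[2:].min()


class TestAdaptiveLasso:
    def test_huge_lambda_empties_selection(self):
        design = toy_design()
        w = pd.Series(1.0, index=design.analytes)
        _, selected, coefs, _ = adaptive_lasso(design, w, lambda_grid=[1e4])
        assert selected == []
        assert np.allclose(coefs, 0.0)

    def test_capped_weight_column_never_selected(self):
        design = toy_design(n=60, p=6, n_signal=3, seed=8)
        w = pd.Series(1.0, index=design.analytes)
        w.iloc[0] = solvers.WEIGHT_CAP
        _, selected, _, _ = adaptive_lasso(design, w)
        assert design.analytes[0] not in selected

    def test_all_capped_weights_warn_and_empty(self):
        design = toy_design()
        w = pd.Series(solvers.WEIGHT_CAP, index=design.analytes)
        with pytest.warns(UserWarning, match="cap"):
            _, selected, _, _ = adaptive_lasso(design, w)
        assert selected == []


class TestJackknifeAndSignature:
    def test_dominant_predictor_selected_in_every_fold(self):
        design = toy_design(n=50, p=5, n_signal=1, seed=12, effect=4.0)
        w = pd.Series(1.0, index=design.analytes)
        lam, selected, coefs, b0 = adaptive_lasso(
            design, w, lambda_grid=np.geomspace(0.5, 1e-3, 20)
        )
        assert design.analytes[0] in selected
        freq, n_failed = jackknife_frequencies(design, w, lam, coefs, b0)
        assert n_failed == 0
        assert freq[design.analytes[0]] == pytest.approx(1.0)
        assert freq.between(0, 1).all()

    @pytest.mark.parametrize(
        "freqs, expected",
        [({"a": 0.90, "b": 0.91, "c": 0.5}, ["b"]), ({}, [])],
    )
    def test_final_signature_strict_threshold(self, freqs, expected):
        assert final_signature(pd.Series(freqs, dtype=float)) == expected

    def test_out_of_range_frequency_rejected(self):
        with pytest.raises(ValueError):
            final_signature(pd.Series({"a": 1.2}))


class TestRunSelection:
    def test_deterministic_and_recovers_planted_signal(self):
        design = toy_design(n=60, p=15, n_signal=2, seed=3, effect=2.0)
        grids = dict(ridge_grid=np.geomspace(10, 1e-3, 15),
                     alasso_grid=np.geomspace(0.3, 1e-3, 15))
        a = run_selection(design, **grids)
        b = run_selection(design, **grids)
        assert a.frequency.equals(b.frequency)
        assert a.lambda_alasso == b.lambda_alasso
        assert set(design.analytes[:2]) <= set(a.full_fit_selected)
        report = a.report()
        assert report["in_signature"].sum() == len(a.signature)
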