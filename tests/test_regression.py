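"""LASSO on contrasts, PGLS, AICc selection, and model averaging."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from phyloniche import brownian_covariance, pgls_fit, pic
from phyloniche.regression import (
    ContrastDesign,
    NotPositiveDefiniteError,
    SingularDesignError,
    enumerate_models,
    kkt_residual,
    lasso_fit,
    lasso_screen,
    model_average,
    pgls_fit_arrays,
    select_best,
    significance_gate,
)
from phyloniche.simulate import simulate_bm, simulate_tree

from conftest import random_yule_tree


def random_design(rng, m=30, p=8):
    X = rng.normal(size=(m, p))
    beta = np.zeros(p)
    beta[:2] = [1.5, -0.8]
    y = X @ beta + rng.normal(scale=0.5, size=m)
    return ContrastDesign(y, X, tuple(f"x{i}" for i in range(p)))


class TestLassoFit:
    def test_unpenalized_limit_equals_ols_through_origin(self, rng):
        d = random_design(rng)
        beta = lasso_fit(d, 0.0)
        ols = np.linalg.lstsq(d.X, d.y, rcond=None)[0]
        np.testing.assert_allclose(beta, ols, atol=1e-8)

    def test_above_null_threshold_all_zero(self, rng):
        d = random_design(rng)
        s = np.sqrt((d.X**2).mean(axis=0))
        lam_max = np.abs((d.X / s).T @ d.y).max() / d.n_obs
        beta = lasso_fit(d, lam_max * 1.0001)
        np.testing.assert_array_equal(beta, np.zeros(d.X.shape[1]))

    def test_univariate_soft_threshold_closed_form(self, rng):
        m = 40
        x = rng.normal(size=(m, 1))
        x /= np.sqrt((x**2).mean())          # unit RMS: already standardized
        y = 2.0 * x[:, 0] + rng.normal(size=m)
        d = ContrastDesign(y, x, ("x",))
        rho = float(x[:, 0] @ y) / m
        for lam in (0.1, 0.5, abs(rho) * 0.9):
            expected = np.sign(rho) * max(abs(rho) - lam, 0.0)
            assert lasso_fit(d, lam)[0] == pytest.approx(expected, abs=1e-8)

    @pytest.mark.parametrize("lam", [0.01, 0.1, 0.5])
    def test_kkt_residuals_small_on_random_problems(self, rng, lam):
        for _ in range(5):
            d = random_design(rng)
            beta = lasso_fit(d, lam)
            assert kkt_residual(d, lam, beta) <= 1e-6

    def test_all_zero_column_forced_to_zero_with_warning(self, rng):
        X = rng.normal(size=(20, 3))
        X[:, 1] = 0.0
        d = ContrastDesign(X @ [1.0, 0.0, -1.0], X, ("a", "b", "c"))
        with pytest.warns(UserWarning, match="b"):
            beta = lasso_fit(d, 0.05)
        assert beta[1] == 0.0


class TestLassoScreen:
    def test_deterministic_given_seed(self, rng):
        d = random_design(rng, m=40, p=20)
        f1 = lasso_screen(d, folds=5, seed=11)
        f2 = lasso_screen(d, folds=5, seed=11)
        assert f1.lam == f2.lam
        np.testing.assert_array_equal(f1.coef, f2.coef)
        assert f1.selected == f2.selected

    def test_planted_predictor_found(self, rng):
        d = random_design(rng, m=60, p=25)
        f = lasso_screen(d, folds=10, seed=0)
        assert "x0" in f.selected and "x1" in f.selected

    def test_no_predictors_rejected(self, rng):
        d = ContrastDesign(rng.normal(size=10), np.empty((10, 0)), ())
        with pytest.raises(ValueError, match="no predictors"):
            lasso_screen(d)

    def test_invalid_fold_count_rejected(self, rng):
        d = random_design(rng, m=10)
        with pytest.raises(ValueError, match="folds"):
            lasso_screen(d, folds=11)


class TestPgls:
    def test_star_phylogeny_reduces_to_ols(self, rng):
        n = 20
        C = np.eye(n)
        X = rng.normal(size=(n, 2))
        y = 1.0 + X @ [2.0, -1.0] + rng.normal(size=n)
        fit = pgls_fit_arrays(y, X, ["a", "b"], C)
        ols = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(fit.beta, ols.params, atol=1e-8)
        np.testing.assert_allclose(fit.se, ols.bse, atol=1e-8)
        np.testing.assert_allclose(fit.pvals, ols.pvalues, atol=1e-8)

    def test_matches_statsmodels_gls_under_tree_covariance(self, rng):
        tree = random_yule_tree(16, 5)
        C = brownian_covariance(tree)
        x = simulate_bm(tree, 1.0, rng)[0].to_numpy()
        y = 2.0 + 0.7 * x + np.linalg.cholesky(C) @ rng.normal(size=16)
        fit = pgls_fit_arrays(y, x[:, None], ["x"], C)
        gls = sm.GLS(y, sm.add_constant(x), sigma=C).fit()
        np.testing.assert_allclose(fit.beta, gls.params, atol=1e-8)
        np.testing.assert_allclose(fit.se, gls.bse, atol=1e-8)

    def test_ml_loglik_matches_multivariate_normal_density(self, rng):
        tree = random_yule_tree(12, 9)
        C = brownian_covariance(tree)
        x = simulate_bm(tree, 1.0, rng)[0].to_numpy()
        y = 1.0 + x + np.linalg.cholesky(C) @ rng.normal(size=12)
        fit = pgls_fit_arrays(y, x[:, None], ["x"], C)
        mean = np.column_stack([np.ones(12), x]) @ fit.beta
        oracle = stats.multivariate_normal.logpdf(y, mean, fit.sigma2 * C)
        assert fit.loglik == pytest.approx(oracle, abs=1e-8)

    def test_aicc_arithmetic(self, rng):
        fit = pgls_fit_arrays(rng.normal(size=15), rng.normal(size=(15, 2)),
                              ["a", "b"], np.eye(15))
        k, n = fit.k, fit.n
        assert fit.aicc == pytest.approx(
            -2 * fit.loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        )

    def test_noiseless_response_recovered_exactly(self, rng):
        X = rng.normal(size=(12, 2))
        y = 3.0 + X @ [1.0, -2.0]
        fit = pgls_fit_arrays(y, X, ["a", "b"], np.eye(12))
        assert fit.degenerate
        np.testing.assert_allclose(fit.beta, [3.0, 1.0, -2.0], atol=1e-10)

    def test_collinear_design_names_columns(self, rng):
        X = rng.normal(size=(15, 2))
        X = np.column_stack([X, X[:, 0]])
        with pytest.raises(SingularDesignError, match="dup"):
            pgls_fit_arrays(rng.normal(size=15), X, ["a", "b", "dup"], np.eye(15))

    def test_non_positive_definite_covariance_rejected(self, rng):
        C = -np.eye(8)
        with pytest.raises(NotPositiveDefiniteError):
            pgls_fit_arrays(rng.normal(size=8), rng.normal(size=(8, 1)), ["x"], C)

    def test_species_joining_drops_mismatches_with_warning(self):
        tree = random_yule_tree(8, 2)
        tips = tree.tip_labels
        rng = np.random.default_rng(0)
        y = pd.Series(rng.normal(size=7), index=tips[:7])
        x = pd.Series(rng.normal(size=8), index=tips)
        with pytest.warns(UserWarning, match=tips[7]):
            fit = pgls_fit(y, {"x": x}, tree)
        assert fit.n == 7

    def test_pic_pgls_slope_equivalence(self, rng):
        """Through-origin contrast regression equals Brownian PGLS (classic)."""
        tree = random_yule_tree(24, 13)
        x = simulate_bm(tree, 1.0, rng)[0]
        y = simulate_bm(tree, 1.0, rng)[0] + 0.5 * x
        cx = pic(tree, x.to_dict()).values
        cy = pic(tree, y.to_dict()).values
        slope_pic = float(cx @ cy / (cx @ cx))
        fit = pgls_fit(y, {"x": x}, tree)
        assert fit.beta[1] == pytest.approx(slope_pic, abs=1e-8)


class TestModelEnumeration:
    def test_subset_counts(self):
        assert len(enumerate_models(["a", "b"])) == 4
        assert len(enumerate_models([])) == 1
        six = ["NOGF_Exosome", "G", "N_g", "N_d", "M", "B_c"]
        assert len(enumerate_models(six)) == 64

    def test_guard_against_blowup(self):
        with pytest.raises(ValueError, match="screen"):
            enumerate_models([f"x{i}" for i in range(17)])

    def test_order_deterministic(self):
        assert enumerate_models(["a", "b"]) == [(), ("a",), ("b",), ("a", "b")]


def make_fit(aicc, k=3, predictors=("x",)):
    """A minimal PGLSFit-like stand-in for selection arithmetic tests."""
    from phyloniche.regression import PGLSFit

    return PGLSFit(
        names=("(Intercept)",) + tuple(predictors),
        beta=np.ones(1 + len(predictors)),
        se=np.full(1 + len(predictors), 0.5),
        tvals=np.ones(1 + len(predictors)),
        pvals=np.full(1 + len(predictors), 0.5),
        loglik=-(aicc / 2), sigma2=1.0, k=k, n=20,
        aicc=aicc, df_resid=20 - k, predictors=tuple(predictors),
    )


class TestSelectionAndAveraging:
    def test_minimum_aicc_selected(self):
        best = select_best([make_fit(97.5), make_fit(84.7, predictors=("y",))])
        assert best.aicc == 84.7

    def test_single_fit_selected(self):
        fit = make_fit(10.0)
        assert select_best([fit]) is fit

    def test_tie_broken_by_fewer_parameters(self):
        small = make_fit(50.0, k=2, predictors=())
        big = make_fit(50.0, k=4, predictors=("x", "y"))
        assert select_best([big, small]) is small

    def test_weights_for_delta_two(self):
        avg = model_average([make_fit(10.0), make_fit(12.0, predictors=("y",))])
        np.testing.assert_allclose(avg.weight, [0.73106, 0.26894], atol=1e-4)
        assert avg.weight.sum() == pytest.approx(1.0, abs=1e-12)

    def test_confidence_set_prefix_rule(self):
        # weights 0.6/0.3/0.08/0.02 from deltas -2 ln(w/w0)
        deltas = -2 * np.log(np.array([0.6, 0.3, 0.08, 0.02]) / 0.6)
        fits = [make_fit(100.0 + d, predictors=(f"x{i}",))
                for i, d in enumerate(deltas)]
        avg = model_average(fits, conf=0.95)
        assert avg.in_set.tolist() == [True, True, True, False]

    def test_confidence_set_matches_exhaustive_minimum(self, rng):
        """The flagged set is the smallest weight-ordered prefix reaching the
        confidence level, verified against brute-force enumeration."""
        import itertools

        for trial in range(10):
            aiccs = rng.uniform(50, 60, size=rng.integers(2, 6))
            fits = [make_fit(a, predictors=(f"x{i}",))
                    for i, a in enumerate(aiccs)]
            avg = model_average(fits, conf=0.95)
            chosen = frozenset(np.flatnonzero(avg.in_set))
            candidates = [
                s for r in range(1, len(fits) + 1)
                for s in itertools.combinations(range(len(fits)), r)
                if avg.weight[list(s)].sum() >= 0.95
            ]
            min_size = min(len(s) for s in candidates)
            assert len(chosen) == min_size
            assert avg.weight[list(chosen)].sum() >= 0.95

    def test_single_model_average_is_identity(self):
        fit = make_fit(10.0)
        avg = model_average([fit])
        np.testing.assert_allclose(avg.beta_full, fit.beta)
        np.testing.assert_allclose(avg.beta_cond, fit.beta)

    def test_zero_substitution_shrinks_full_average(self):
        with_x = make_fit(10.0, predictors=("x",))
        without = make_fit(10.5, predictors=())
        avg = model_average([with_x, without])
        j = avg.terms.index("x")
        assert 0 < avg.beta_full[j] < avg.beta_cond[j] + 1e-12
        assert avg.beta_cond[j] == pytest.approx(1.0)

    def test_invalid_confidence_rejected(self):
        with pytest.raises(ValueError):
            model_average([make_fit(1.0)], conf=1.5)


class TestSignificanceGate:
    @pytest.mark.parametrize("p,expected", [(0.009, True), (0.01, False),
                                            (0.5, False), (0.0, True)])
    def test_strict_threshold(self, p, expected):
        assert significance_gate(p) is expected

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            significance_gate(1.5)
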