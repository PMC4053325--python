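"""GWR engine: kernels, local fits against hand linear algebra, global
limits, bandwidth selection, the F comparison, and the permutation test."""
import math

import numpy as np
import pytest
import statsmodels.api as sm

from lekscape import gwr
from lekscape.errors import ContractError

from conftest import random_gwr_instance


def make_design(coords, X, y, **kw):
    return gwr.GWRDesign(y=y, X=X, coords=coords, **kw)


class TestKernels:
    def test_self_weight_is_one(self):
        coords = np.array([[0.0, 0.0], [100.0, 0.0]])
        for kernel in ("gaussian", "bisquare"):
            w = gwr.kernel_weights(coords, 0, 500.0, kernel)
            assert w[0] == 1.0

    def test_bisquare_half_bandwidth(self):
        coords = np.array([[0.0, 0.0], [50.0, 0.0]])
        w = gwr.kernel_weights(coords, 0, 100.0, "bisquare")
        assert w[1] == pytest.approx(0.5625)  # (1 - 0.25)^2

    def test_bisquare_vanishes_at_and_beyond_bandwidth(self):
        coords = np.array([[0.0, 0.0], [100.0, 0.0], [250.0, 0.0]])
        w = gwr.kernel_weights(coords, 0, 100.0, "bisquare")
        assert w[1] == 0.0 and w[2] == 0.0

    def test_gaussian_form(self):
        coords = np.array([[0.0, 0.0], [100.0, 0.0]])
        w = gwr.kernel_weights(coords, 0, 100.0, "gaussian")
        assert w[1] == pytest.approx(math.exp(-0.5))

    def test_adaptive_bandwidth_reaches_kth_neighbour(self):
        coords = np.column_stack([np.arange(5) * 100.0, np.zeros(5)])
        w = gwr.kernel_weights(coords, 0, 3, "bisquare", adaptive=True)
        # b = distance to 3rd nearest (incl. self) = 200 m
        assert w[1] == pytest.approx((1 - 0.25) ** 2)
        assert w[2] == 0.0  # exactly at b


class TestFitLocal:
    def test_uniform_weights_equal_global_ols(self):
        rng = np.random.default_rng(1)
        coords, X, y = random_gwr_instance(rng, 30)
        beta, _ = gwr.fit_local(X, y, np.ones(30))
        ref = sm.OLS(y, X).fit()
        np.testing.assert_allclose(beta, ref.params, atol=1e-10)

    def test_hand_computed_five_point_system(self):
        # five points, two columns, explicit weights; the oracle is the
        # normal-equation solution assembled element by element
        X = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0], [1.0, 3.0], [1.0, 4.0]])
        y = np.array([1.0, 2.0, 2.5, 4.0, 4.5])
        w = np.array([1.0, 0.8, 0.5, 0.2, 0.1])
        sw = w.sum()
        swx = (w * X[:, 1]).sum()
        swxx = (w * X[:, 1] ** 2).sum()
        swy = (w * y).sum()
        swxy = (w * X[:, 1] * y).sum()
        det = sw * swxx - swx**2
        expected = np.array(
            [(swxx * swy - swx * swxy) / det, (sw * swxy - swx * swy) / det]
        )
        beta, _ = gwr.fit_local(X, y, w)
        np.testing.assert_allclose(beta, expected, atol=1e-10)

    def test_constant_response_gives_flat_fit(self):
        rng = np.random.default_rng(2)
        coords, X, _ = random_gwr_instance(rng, 20)
        beta, _ = gwr.fit_local(X, np.full(20, 3.25), rng.uniform(0.1, 1, 20))
        assert beta[0] == pytest.approx(3.25, abs=1e-9)
        np.testing.assert_allclose(beta[1:], 0.0, atol=1e-9)


class TestFitGWR:
    def test_huge_bandwidth_recovers_global_ols(self):
        rng = np.random.default_rng(3)
        coords, X, y = random_gwr_instance(rng, 40)
        design = make_design(coords, X, y)
        fit = gwr.fit_gwr(design, "gaussian", 1e12)
        beta_glob, _ = gwr.global_ols(X, y)
        assert np.max(np.abs(fit.local_beta - beta_glob)) < 1e-6
        assert fit.effective_params == pytest.approx(X.shape[1], abs=1e-6)

    def test_rows_match_independent_local_fits(self):
        rng = np.random.default_rng(4)
        coords, X, y = random_gwr_instance(rng, 25)
        design = make_design(coords, X, y)
        fit = gwr.fit_gwr(design, "bisquare", 6000.0)
        for i in (0, 7, 24):
            w = gwr.kernel_weights(coords, i, 6000.0, "bisquare")
            beta, se = gwr.fit_local(X, y, w, error_variance=fit.sigma2)
            np.testing.assert_allclose(fit.local_beta[i], beta, atol=1e-8)
            np.testing.assert_allclose(fit.local_se[i], se, atol=1e-8)

    def test_hat_trace_within_bounds_and_t_consistent(self):
        rng = np.random.default_rng(5)
        coords, X, y = random_gwr_instance(rng, 30)
        fit = gwr.fit_gwr(make_design(coords, X, y), "bisquare", 15, adaptive=True)
        assert 1.0 <= fit.hat_trace <= 30.0
        mask = fit.local_se > 0
        np.testing.assert_allclose(
            fit.local_t[mask], (fit.local_beta / fit.local_se)[mask], atol=1e-12
        )
        assert fit.rss >= 0

    def test_step_field_localised(self):
        # strongly nonstationary slope: -4 west of the midline, 0 east
        rng = np.random.default_rng(6)
        n = 120
        coords = rng.uniform(0, 10_000, (n, 2))
        d = rng.uniform(0, 2, n)
        beta_true = np.where(coords[:, 0] < 5_000, -4.0, 0.0)
        y = 10.0 + beta_true * d
        design = make_design(coords, np.column_stack([np.ones(n), d]), y)
        bw = gwr.select_bandwidth(design, "bisquare", "adaptive")
        fit = gwr.fit_gwr(design, "bisquare", bw, adaptive=True)
        off_step = np.abs(coords[:, 0] - 5_000) > 1_000
        slopes = fit.local_beta[off_step, 1]
        truth = beta_true[off_step]
        correct = ((slopes < -2.0) & (truth < 0)) | ((np.abs(slopes) < 2.0) & (truth == 0))
        assert correct.mean() >= 0.9


class TestBinomialFamily:
    def test_huge_bandwidth_recovers_global_logistic(self):
        rng = np.random.default_rng(7)
        n = 200
        coords = rng.uniform(0, 10_000, (n, 2))
        x = rng.normal(0, 1, n)
        X = np.column_stack([np.ones(n), x])
        p = 1 / (1 + np.exp(-(0.5 + 1.2 * x)))
        y = (rng.uniform(size=n) < p).astype(float)
        design = make_design(coords, X, y, family="binomial")
        fit = gwr.fit_gwr(design, "gaussian", 1e12)
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.local_beta[0], ref.params, atol=1e-5)
        np.testing.assert_allclose(fit.local_se[0], ref.bse, rtol=1e-3)
        assert 0 <= fit.pseudo_r2 <= 1


class TestSelectBandwidth:
    def test_deterministic(self):
        rng = np.random.default_rng(8)
        coords, X, y = random_gwr_instance(rng, 40)
        design = make_design(coords, X, y)
        b1 = gwr.select_bandwidth(design, "bisquare", "adaptive")
        b2 = gwr.select_bandwidth(design, "bisquare", "adaptive")
        assert b1 == b2

    def test_stationary_data_pushes_to_global(self):
        rng = np.random.default_rng(9)
        coords, X, y = random_gwr_instance(rng, 60)  # globally linear truth
        design = make_design(coords, X, y)
        k = gwr.select_bandwidth(design, "bisquare", "adaptive")
        assert k >= 0.7 * 60

    def test_step_field_pulls_bandwidth_down(self):
        rng = np.random.default_rng(10)
        n = 150
        coords = rng.uniform(0, 10_000, (n, 2))
        d = rng.uniform(0, 2, n)
        y = 5.0 + np.where(coords[:, 0] < 5_000, -4.0, 0.0) * d
        design = make_design(coords, np.column_stack([np.ones(n), d]), y)
        bw = gwr.select_bandwidth(design, "bisquare", "fixed")
        diag = math.hypot(np.ptp(coords[:, 0]), np.ptp(coords[:, 1]))
        assert bw < diag / 4

    def test_too_few_points_rejected(self):
        rng = np.random.default_rng(11)
        coords, X, y = random_gwr_instance(rng, 7, p=3)
        with pytest.raises(ContractError):
            gwr.select_bandwidth(make_design(coords, X, y))


class TestAnova:
    def _dummy_fit(self, rss, eff, n=200):
        rng = np.random.default_rng(0)
        coords, X, y = random_gwr_instance(rng, 20)
        fit = gwr.fit_gwr(make_design(coords, X, y), "gaussian", 1e12)
        fit.rss = rss
        fit.effective_params = eff
        return fit

    def test_identical_models_give_f_zero_p_one(self):
        fit = self._dummy_fit(rss=500.0, eff=13.0, n=200)
        res = gwr.anova_vs_global(fit, global_rss=500.0, n=200, p=3)
        assert res.F == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_hand_built_fixture(self):
        # RSS 1000 vs 800 with df 10 and 180: F = (200/10)/(800/180) = 4.5
        fit = self._dummy_fit(rss=800.0, eff=13.0)
        res = gwr.anova_vs_global(fit, global_rss=1000.0, n=193, p=3)
        assert res.F == pytest.approx(4.5)
        assert 0 < res.p_value < 1

    def test_undefined_when_no_extra_params(self):
        fit = self._dummy_fit(rss=800.0, eff=3.0)
        res = gwr.anova_vs_global(fit, global_rss=1000.0, n=200, p=3)
        assert not res.defined
        assert math.isnan(res.F)


class TestMonteCarlo:
    def test_stationary_global_fit_gives_large_p(self):
        rng = np.random.default_rng(12)
        coords, X, y = random_gwr_instance(rng, 30)
        design = make_design(coords, X, y)
        res = gwr.monte_carlo_nonstationarity(design, "gaussian", 1e12, 49, seed=1)
        # with a global bandwidth the local betas barely vary; permuting
        # coordinates changes nothing material
        assert np.all(res.p_values > 0.2)

    def test_step_covariate_detected(self):
        rng = np.random.default_rng(13)
        n = 80
        coords = rng.uniform(0, 10_000, (n, 2))
        d = rng.uniform(0, 2, n)
        y = 5.0 + np.where(coords[:, 0] < 5_000, -4.0, 0.0) * d + rng.normal(0, 0.5, n)
        design = make_design(coords, np.column_stack([np.ones(n), d]), y)
        res = gwr.monte_carlo_nonstationarity(
            design, "bisquare", 25, 99, seed=2, adaptive=True
        )
        assert res.p_values[1] <= 0.05

    def test_p_value_formula_and_determinism(self):
        rng = np.random.default_rng(14)
        coords, X, y = random_gwr_instance(rng, 25)
        design = make_design(coords, X, y)
        a = gwr.monte_carlo_nonstationarity(design, "bisquare", 15, 49, seed=3,
                                            adaptive=True)
        b = gwr.monte_carlo_nonstationarity(design, "bisquare", 15, 49, seed=3,
                                            adaptive=True)
        np.testing.assert_array_equal(a.p_values, b.p_values)
        expected = (1 + (a.permuted >= a.observed).sum(axis=0)) / (1 + 49)
        np.testing.assert_allclose(a.p_values, expected)
        assert np.all(a.p_values > 0) and np.all(a.p_values <= 1)

    def test_too_few_permutations_rejected(self):
        rng = np.random.default_rng(15)
        coords, X, y = random_gwr_instance(rng, 25)
        with pytest.raises(ContractError):
            gwr.monte_carlo_nonstationarity(
                make_design(coords, X, y), "bisquare", 15, 5, seed=0
            )


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_instances(self):
        """Local coefficients equal an independent per-lek weighted
        normal-equation solve (assembled with explicit loops)."""
        rng = np.random.default_rng(16)
        for _ in range(10):
            n = int(rng.integers(10, 50))
            coords, X, y = random_gwr_instance(rng, n)
            bw = float(rng.uniform(2000, 20000))
            fit = gwr.fit_gwr(make_design(coords, X, y), "gaussian", bw)
            for i in range(0, n, max(1, n // 5)):
                d = np.sqrt(((coords - coords[i]) ** 2).sum(axis=1))
                w = np.exp(-0.5 * (d / bw) ** 2)
                A = np.zeros((3, 3))
                b = np.zeros(3)
                for k in range(n):
                    A += w[k] * np.outer(X[k], X[k])
                    b += w[k] * X[k] * y[k]
                np.testing.assert_allclose(
                    fit.local_beta[i], np.linalg.solve(A, b), atol=1e-8
                )
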