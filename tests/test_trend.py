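"""LOWESS periodicity correction and trend responses."""
import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from lekscape import trend
from lekscape.errors import ContractError
from lekscape.types import AnalysisConfig, LekSeries, LekYear

YEARS10 = np.arange(2002, 2012)


class TestLowessMatrix:
    def test_matches_classical_lowess(self):
        """The explicit hat-matrix smoother reproduces classical LOWESS
        (robustness iterations off) exactly."""
        rng = np.random.default_rng(0)
        x = np.arange(12.0)
        y = 5 * np.sin(2 * np.pi * x / 6) + rng.normal(0, 2, 12) + 12
        for frac in (0.4, 0.5, 0.7, 1.0):
            S = trend.lowess_matrix(x, frac)
            ref = sm_lowess(y, x, frac=frac, it=0, return_sorted=False)
            np.testing.assert_allclose(S @ y, ref, atol=1e-10)

    def test_preserves_linear_data(self):
        x = np.arange(10.0)
        y = 3.5 * x - 7.0
        for frac in (0.5, 0.8, 1.0):
            np.testing.assert_allclose(trend.lowess_matrix(x, frac) @ y, y, atol=1e-6)

    def test_evaluates_at_new_points(self):
        x = np.arange(0, 10, 2.0)
        y = 2 * x + 1
        S = trend.lowess_matrix(x, 1.0, x_eval=np.array([1.0, 3.0]))
        np.testing.assert_allclose(S @ y, [3.0, 7.0], atol=1e-8)


class TestSpanSelection:
    def test_noisy_sinusoid_prefers_sub_maximal_span(self):
        """On a periodic signal the AICc grid search must trade smoothness
        for fidelity: the chosen span is strictly below the grid maximum and
        matches an independent re-run of the criterion with classical LOWESS
        fits."""
        rng = np.random.default_rng(4)
        y = 5 * np.sin(2 * np.pi * YEARS10 / 6) + rng.normal(0, 2, 10) + 15
        span = trend.select_lowess_span(YEARS10, y)
        assert span < 1.0
        # independent oracle: RSS from statsmodels fits, k from the hat trace
        def aicc_of(frac):
            fit = sm_lowess(y, YEARS10.astype(float), frac=frac, it=0,
                            return_sorted=False)
            rss = max(float(((y - fit) ** 2).sum()), 1e-12)
            k = float(np.trace(trend.lowess_matrix(YEARS10.astype(float), frac)))
            n = len(y)
            return n * math.log(rss / n) + 2 * k * n / (n - k - 1) if n - k - 1 > 0 else math.inf

        grid = trend.DEFAULT_SPAN_GRID
        best = min(grid, key=lambda f: (round(aicc_of(f), 9), f))
        assert span == best

    def test_constant_series_breaks_tie_to_smallest_span(self):
        """Every genuine smoothing span fits a constant series perfectly;
        the tie breaks to the smallest such span (degenerate windows that
        merely interpolate do not count as smoothing)."""
        span = trend.select_lowess_span(YEARS10, np.full(10, 8.0))
        smoothing_spans = [
            f for f in trend.DEFAULT_SPAN_GRID
            if np.trace(trend.lowess_matrix(YEARS10.astype(float), f)) <= 8
        ]
        assert span == min(smoothing_spans)
        out = trend.lowess_logit_smooth(YEARS10, np.full(10, 8.0), span)
        np.testing.assert_allclose(out, 8.0, atol=1e-8)

    def test_too_few_points_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="maximal span"):
            span = trend.select_lowess_span([2008, 2009, 2010, 2011], [1, 2, 3, 4])
        assert span == trend.DEFAULT_SPAN_GRID[-1]


class TestLogitSmooth:
    def test_smooth_positive_series_nearly_reproduced(self):
        y = 20 + 0.5 * (YEARS10 - 2002)
        out = trend.lowess_logit_smooth(YEARS10, y, span=0.5)
        np.testing.assert_allclose(out, y, rtol=0.05)

    def test_pure_oscillation_is_damped(self):
        y = np.array([10, 14] * 5, dtype=float)
        out = trend.lowess_logit_smooth(YEARS10, y, span=1.0)
        assert np.all(out > 10.0) and np.all(out < 14.0)

    def test_all_zero_series_stays_zero(self):
        out = trend.lowess_logit_smooth(YEARS10, np.zeros(10), span=0.5)
        np.testing.assert_array_equal(out, np.zeros(10))

    def test_output_bounded_by_count_range(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            y = rng.poisson(8, 10).astype(float)
            if y.max() == 0:
                continue
            out = trend.lowess_logit_smooth(YEARS10, y, span=0.6)
            assert np.all(out >= 0.0) and np.all(out < y.max() + 1)

    def test_fills_unsurveyed_years(self):
        obs_years = [2002, 2004, 2006, 2008, 2010]
        y = [10, 12, 14, 16, 18]
        out = trend.lowess_logit_smooth(obs_years, y, span=1.0,
                                        eval_years=list(YEARS10))
        assert out.shape == (10,)
        assert np.all(np.isfinite(out))

    def test_logit_linear_series_recovered_exactly(self):
        """A series linear on the logit scale is in the smoother's own model
        class and survives the transform chain unchanged."""
        z = -1.0 + 0.25 * (YEARS10 - 2002)
        p = 1 / (1 + np.exp(-z))
        # choose the series maximum self-consistently with the empirical
        # mapping p = (c + 0.5) / (c_max + 1), i.e. c_max = (p_max-.5)/(1-p_max)
        c_max = (p.max() - 0.5) / (1 - p.max())
        counts = p * (c_max + 1) - 0.5
        assert counts.max() == pytest.approx(c_max)
        out = trend.lowess_logit_smooth(YEARS10, counts, span=1.0)
        np.testing.assert_allclose(out, counts, atol=1e-8)


class TestWindowTrend:
    def test_exact_line(self):
        resp = trend.window_trend(range(2007, 2012), [10, 8, 6, 4, 2], 5, 2011)
        assert resp.value == pytest.approx(-2.0)
        assert resp.kind == "trend5"
        assert (resp.window_start_year, resp.window_end_year) == (2007, 2011)

    def test_constant_series_zero_slope(self):
        resp = trend.window_trend(range(2002, 2012), [7.0] * 10, 10, 2011)
        assert resp.value == pytest.approx(0.0, abs=1e-12)

    @given(st.lists(st.floats(-50, 50), min_size=10, max_size=10))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_closed_form_slope(self, values):
        resp = trend.window_trend(YEARS10, values, 10, 2011)
        x = YEARS10 - YEARS10.mean()
        y = np.asarray(values)
        expected = float((x * (y - y.mean())).sum() / (x * x).sum())
        assert resp.value == pytest.approx(expected, abs=1e-9)

    def test_reflection_negates_slope(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 30, 10)
        fwd = trend.window_trend(YEARS10, vals, 10, 2011).value
        rev = trend.window_trend(YEARS10, vals[::-1], 10, 2011).value
        assert fwd == pytest.approx(-rev, abs=1e-9)

    def test_missing_years_is_contract_error(self):
        with pytest.raises(ContractError, match="missing years"):
            trend.window_trend([2009, 2011], [1.0, 2.0], 3, 2011)


class TestBinaryResponse:
    @pytest.mark.parametrize("slope,expected", [(-1.89, 0.0), (3.2, 1.0), (0.0, 0.0)])
    def test_sign_rule(self, slope, expected):
        t = trend.window_trend(range(2007, 2012),
                               [slope * (y - 2007) for y in range(2007, 2012)],
                               5, 2011, lek_id="A")
        assert trend.binary_response(t).value == expected

    def test_requires_trend_input(self):
        from lekscape.types import TrendResponse

        bad = TrendResponse("A", "adjusted_final_count", 12.0, 2002, 2011)
        with pytest.raises(ContractError):
            trend.binary_response(bad)


class TestFullStack:
    @pytest.mark.parametrize("slope", [-3.0, -0.5, 0.0, 1.25])
    @pytest.mark.parametrize("window", [3, 5, 10])
    def test_linear_series_slope_recovered_on_count_scale(self, slope, window):
        """Smoothing (count scale) then windowed regression is unbiased on
        noiseless linear attendance: the local-linear smoother preserves
        straight lines exactly."""
        counts = 40.0 + slope * (YEARS10 - 2002)
        span = trend.select_lowess_span(YEARS10, counts)
        adjusted = trend.lowess_logit_smooth(YEARS10, counts, span,
                                             fit_scale="count")
        resp = trend.window_trend(YEARS10, adjusted, window, 2011)
        assert resp.value == pytest.approx(slope, abs=1e-6)

    def test_lek_responses_produces_all_kinds(self):
        rng = np.random.default_rng(6)
        lek = LekSeries(
            lek_id="A", x=0, y=0,
            records={int(y): LekYear(males=float(c))
                     for y, c in zip(YEARS10, rng.poisson(15, 10))},
        )
        out = trend.lek_responses(lek, 2011, AnalysisConfig())
        assert set(out) == {"trend3", "trend5", "trend10",
                            "adjusted_final_count", "binary"}
        assert out["binary"].value in (0.0, 1.0)
        assert out["adjusted_final_count"].value >= 0.0
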