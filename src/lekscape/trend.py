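"""Periodicity correction of lek-count series and trend-response construction.

Lek counts cycle over 3-5 year horizons, so raw short-window regressions
confound the cycle with the trend.  The correction: map counts to empirical
proportions of the lek's maximum, logit-transform, smooth over years with a
local-linear tricube (LOWESS) smoother whose span is chosen by corrected AIC,
and back-transform.  Windowed OLS slopes of the smoothed series are the
trend responses (3-, 5- and 10-year), alongside the smoothed final-year
count and a binary increasing/decreasing indicator.

The smoother here is written as an explicit linear operator (hat matrix) so
that its trace — the effective number of parameters — is available for the
AICc criterion.  With robustness iterations off it reproduces the classical
LOWESS fit exactly.
"""
from __future__ import annotations

import math
import warnings
from typing import Optional, Sequence

import numpy as np

from .errors import ContractError
from .types import AnalysisConfig, LekSeries, TrendResponse

DEFAULT_SPAN_GRID = (0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


def lowess_matrix(x: np.ndarray, span: float, x_eval: Optional[np.ndarray] = None) -> np.ndarray:
    """Linear smoother matrix S of local-linear tricube smoothing.

    Row ``i`` of ``S`` gives the weights producing the fit at ``x_eval[i]``
    (default: the data points themselves), so ``fitted = S @ y``.  The local
    window holds ``max(2, floor(span * n))`` nearest neighbours — the
    classical LOWESS convention.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ContractError("smoothing needs at least 2 points")
    if not 0 < span <= 1:
        raise ContractError(f"span must lie in (0, 1], got {span}")
    targets = x if x_eval is None else np.asarray(x_eval, dtype=float)
    r = max(2, int(span * n))
    S = np.empty((targets.size, n))
    for i, t in enumerate(targets):
        d = np.abs(x - t)
        dmax = np.sort(d)[r - 1]
        if dmax == 0:
            w = (d == 0).astype(float)
            w /= w.sum()
            S[i] = w
            continue
        u = np.clip(d / dmax, 0.0, 1.0)
        w = (1 - u**3) ** 3
        A = np.column_stack([np.ones(n), x - t])
        WA = A * w[:, None]
        G = A.T @ WA
        # fit at t is the local intercept: e1^T G^{-1} A^T W; a degenerate
        # window (weight support collapsed onto the focal point) falls back
        # to the minimum-norm solution, which interpolates the focal value —
        # the same convention classical LOWESS uses
        try:
            S[i] = np.linalg.solve(G, WA.T)[0]
        except np.linalg.LinAlgError:
            S[i] = np.linalg.lstsq(G, WA.T, rcond=None)[0][0]
    return S


def lowess_aicc(y: np.ndarray, S: np.ndarray) -> float:
    """Corrected AIC of a linear smoother: n ln(RSS/n) + 2k n/(n-k-1) with
    k = tr(S).  Returns +inf when the correction denominator is not positive."""
    y = np.asarray(y, dtype=float)
    n = y.size
    resid = y - S @ y
    rss = float(resid @ resid)
    k = float(np.trace(S))
    if n - k - 1 <= 0:
        return math.inf
    # floor RSS so noiseless series do not yield -inf; ties then resolve by span
    rss = max(rss, 1e-12)
    return n * math.log(rss / n) + 2 * k * n / (n - k - 1)


def select_lowess_span(
    years: Sequence[int],
    counts: Sequence[float],
    span_grid: Sequence[float] = DEFAULT_SPAN_GRID,
) -> float:
    """Span from ``span_grid`` minimising the smoother's AICc.

    Ties break toward the smaller span.  Fewer than 5 observed years falls
    back to the maximal grid span with a warning.
    """
    years = np.asarray(years, dtype=float)
    counts = np.asarray(counts, dtype=float)
    grid = sorted(span_grid)
    if years.size < 5:
        warnings.warn(
            f"only {years.size} observed years; falling back to maximal span",
            stacklevel=2,
        )
        return grid[-1]
    best_span, best_aicc = None, math.inf
    for span in grid:
        S = lowess_matrix(years, span)
        resid = counts - S @ counts
        rss = float(resid @ resid)
        if rss <= 1e-12 and float(np.trace(S)) <= years.size - 2:
            # a perfect fit by a genuine smoother (constant or straight-line
            # series): every such span is optimal; take the smallest.  A
            # degenerate window that merely interpolates (tr(S) ~ n) does
            # not qualify
            return span
        aicc = lowess_aicc(counts, S)
        if aicc < best_aicc:  # strict: first (smallest) span wins ties
            best_span, best_aicc = span, aicc
    return best_span if best_span is not None else grid[-1]


def _empirical_logit(c: np.ndarray, c_max: float) -> np.ndarray:
    p = (c + 0.5) / (c_max + 1.0)
    return np.log(p / (1 - p))


def _inverse_logit_count(z: np.ndarray, c_max: float) -> np.ndarray:
    p = 1.0 / (1.0 + np.exp(-z))
    return np.maximum(0.0, p * (c_max + 1.0) - 0.5)


def lowess_logit_smooth(
    years: Sequence[int],
    counts: Sequence[float],
    span: float,
    eval_years: Optional[Sequence[int]] = None,
    fit_scale: str = "logit",
) -> np.ndarray:
    """Periodicity-adjusted attendance for every year in ``eval_years``.

    Default path maps counts to proportions ``p = (c + 0.5) / (c_max + 1)``
    of the lek's maximum (the half-count offset keeps the logit finite at 0
    and at the maximum), logit-transforms, LOWESS-smooths over years, and
    back-transforms to the count scale.  ``fit_scale='count'`` instead
    smooths the raw counts and clips at zero, with the logit machinery
    bypassed.  Unsurveyed years inside ``eval_years`` are filled by
    evaluating the smooth there.  Output always lies in [0, c_max + 1).
    """
    years = np.asarray(years, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ContractError("counts must be non-negative")
    targets = years if eval_years is None else np.asarray(eval_years, dtype=float)
    c_max = float(counts.max()) if counts.size else 0.0
    if c_max == 0.0:
        return np.zeros(targets.size)
    S = lowess_matrix(years, span, x_eval=targets)
    if fit_scale == "count":
        return np.clip(S @ counts, 0.0, None)
    z = _empirical_logit(counts, c_max)
    return _inverse_logit_count(S @ z, c_max)


def window_trend(
    years: Sequence[int],
    adjusted: Sequence[float],
    window: int,
    end_year: int,
    lek_id: str = "",
) -> TrendResponse:
    """OLS slope (males/lek/year) of adjusted attendance on year over the
    ``window`` years ending at ``end_year``."""
    start = end_year - window + 1
    lookup = dict(zip((int(y) for y in years), adjusted))
    missing = [y for y in range(start, end_year + 1) if y not in lookup]
    if missing:
        raise ContractError(
            f"adjusted series missing years {missing}; smooth must fill the window first"
        )
    xs = np.arange(start, end_year + 1, dtype=float)
    ys = np.array([lookup[int(y)] for y in xs])
    slope = float(np.polyfit(xs, ys, 1)[0])
    return TrendResponse(
        lek_id=lek_id, kind=f"trend{window}", value=slope,
        window_start_year=start, window_end_year=end_year,
    )


def binary_response(trend: TrendResponse) -> TrendResponse:
    """1 if the trend slope is positive, else 0 (a flat slope counts as not
    increasing)."""
    if not trend.kind.startswith("trend"):
        raise ContractError(f"binary response needs a trend input, got kind {trend.kind!r}")
    return TrendResponse(
        lek_id=trend.lek_id, kind="binary", value=1.0 if trend.value > 0 else 0.0,
        window_start_year=trend.window_start_year, window_end_year=trend.window_end_year,
    )


def lek_responses(
    lek: LekSeries,
    final_year: int,
    config: Optional[AnalysisConfig] = None,
) -> dict[str, TrendResponse]:
    """All response variables for one lek over the decade ending at
    ``final_year``.

    The span is selected once on the surveyed counts inside the 10-year
    window; the smooth then fills every year of the window, and windowed
    trends, the adjusted final-year count, and the binary indicator (from
    the full-decade trend) are derived from it.
    """
    config = config or AnalysisConfig()
    window_start = final_year - 9
    yrs, cnts = lek.counts()
    pairs = [(y, c) for y, c in zip(yrs, cnts) if window_start <= y <= final_year]
    if len(pairs) < 2:
        raise ContractError(f"lek {lek.lek_id}: too few surveyed years in window")
    obs_years = [p[0] for p in pairs]
    obs_counts = [p[1] for p in pairs]
    span = select_lowess_span(obs_years, obs_counts, config.lowess_span_grid)
    all_years = list(range(window_start, final_year + 1))
    adjusted = lowess_logit_smooth(
        obs_years, obs_counts, span, eval_years=all_years,
        fit_scale=config.lowess_fit_scale,
    )
    out: dict[str, TrendResponse] = {}
    for w in config.trend_windows:
        resp = window_trend(all_years, adjusted, w, final_year, lek_id=lek.lek_id)
        out[resp.kind] = resp
    out["adjusted_final_count"] = TrendResponse(
        lek_id=lek.lek_id, kind="adjusted_final_count", value=float(adjusted[-1]),
        window_start_year=window_start, window_end_year=final_year,
    )
    decade_kind = f"trend{max(config.trend_windows)}"
    out["binary"] = binary_response(out[decade_kind])
    return out
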