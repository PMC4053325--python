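"""Geographically weighted regression (GWR) with Monte Carlo nonstationarity
tests.

GWR fits a separate distance-weighted least-squares regression at every
observation point, so coefficients may vary over space.  At focal point i
with kernel weights w_ij,

    beta_i = (X' W_i X)^{-1} X' W_i y,

and the fitted value at i is row i of the smoother matrix S applied to y.
Model complexity is summarised by tr(S) and the effective parameter count
2 tr(S) - tr(S'S); model support by a small-sample corrected AIC.  Spatial
nonstationarity of each coefficient is tested post hoc by permuting the
coordinates against the fixed (y, X) rows and comparing the variance of the
local coefficients with its permutation distribution.

The binomial family is a geographically weighted logistic regression via
local iteratively reweighted least squares.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

from .errors import ContractError, DegenerateDesignError

__all__ = [
    "GWRDesign", "GWRFit", "AnovaResult", "MonteCarloResult",
    "kernel_weights", "fit_local", "select_bandwidth", "fit_gwr",
    "anova_vs_global", "monte_carlo_nonstationarity", "global_ols",
]


@dataclass
class GWRDesign:
    """Aligned response, design matrix (intercept first), coordinates."""

    y: np.ndarray  # (n,)
    X: np.ndarray  # (n, p) including intercept column
    coords: np.ndarray  # (n, 2) planar metres
    family: str = "gaussian"  # {gaussian, binomial}
    covariate_names: list[str] = field(default_factory=list)
    lek_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        n = self.y.size
        if self.X.shape[0] != n or self.coords.shape[0] != n:
            raise ContractError("y, X and coords must have aligned rows")
        if self.family not in ("gaussian", "binomial"):
            raise ContractError(f"unknown family {self.family!r}")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise DegenerateDesignError("global design matrix is rank deficient")
        if not self.covariate_names:
            p = self.X.shape[1]
            self.covariate_names = ["intercept"] + [f"x{j}" for j in range(1, p)]

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class GWRFit:
    """Local estimates and model-level statistics of one GWR fit."""

    bandwidth: float  # metres (fixed) or neighbour count (adaptive)
    kernel: str
    adaptive: bool
    local_beta: np.ndarray  # (n, p)
    local_se: np.ndarray
    local_t: np.ndarray
    hat_trace: float  # tr(S)
    effective_params: float  # 2 tr(S) - tr(S'S) (gaussian); tr(S) (binomial)
    residuals: np.ndarray
    fitted: np.ndarray
    rss: float
    aicc: float
    pseudo_r2: float
    sigma2: float
    design: GWRDesign
    flagged: list[int] = field(default_factory=list)  # rank-deficient/non-convergent leks

    @property
    def n(self) -> int:
        return self.design.n

    @property
    def residual_df(self) -> float:
        return self.n - self.effective_params


@dataclass(frozen=True)
class AnovaResult:
    """Approximate F comparison of a GWR fit against the global model."""

    F: float
    p_value: float
    df_improvement: float
    df_residual: float
    defined: bool = True


@dataclass
class MonteCarloResult:
    """Permutation test of coefficient nonstationarity, one p per covariate."""

    covariate_names: list[str]
    observed: np.ndarray  # (p,) variance over leks of local coefficients
    permuted: np.ndarray  # (n_permutations, p)
    p_values: np.ndarray  # (p,)  p = (1 + #{perm >= obs}) / (1 + n_perm)
    seed: int
    n_permutations: int


# ---------------------------------------------------------------------------
# kernels

def _kernel_from_distance(d: np.ndarray, bandwidth: float, kernel: str) -> np.ndarray:
    if bandwidth <= 0:
        raise ContractError("bandwidth must be positive")
    u = d / bandwidth
    if kernel == "gaussian":
        return np.exp(-0.5 * u**2)
    if kernel == "bisquare":
        w = (1.0 - u**2) ** 2
        return np.where(u < 1.0, w, 0.0)
    raise ContractError(f"unknown kernel {kernel!r}")


def _adaptive_bandwidths(D: np.ndarray, k: int) -> np.ndarray:
    """Per-focal bandwidth: distance to the k-th nearest point (self included)."""
    n = D.shape[0]
    k = int(min(max(k, 2), n))
    b = np.partition(D, k - 1, axis=1)[:, k - 1]
    # duplicated coordinates can give a zero radius; fall back to the nearest
    # strictly positive distance so the focal fit still sees its neighbours
    if np.any(b <= 0):
        pos_min = np.where(D > 0, D, np.inf).min(axis=1)
        b = np.where(b > 0, b, pos_min)
    return b


def _weight_matrix(D: np.ndarray, bandwidth: float, kernel: str, adaptive: bool) -> np.ndarray:
    if adaptive:
        b = _adaptive_bandwidths(D, int(round(bandwidth)))
        return _kernel_from_distance(D / b[:, None], 1.0, kernel)
    return _kernel_from_distance(D, bandwidth, kernel)


def kernel_weights(
    coords: np.ndarray,
    focal_index: int,
    bandwidth: float,
    kernel: str = "bisquare",
    adaptive: bool = False,
) -> np.ndarray:
    """Kernel weight of every observation in the local fit at one focal point.

    Gaussian: ``w = exp(-0.5 (d/b)^2)``.  Bisquare: ``w = (1-(d/b)^2)^2`` for
    ``d < b``, else 0.  The self-weight at d = 0 is 1.  With ``adaptive``
    the bandwidth is a neighbour count and b is the distance to the k-th
    nearest point.
    """
    coords = np.asarray(coords, dtype=float)
    d = np.linalg.norm(coords - coords[focal_index], axis=1)
    if adaptive:
        k = int(min(max(round(bandwidth), 2), coords.shape[0]))
        b = np.sort(d)[k - 1]
        if b <= 0:
            pos = d[d > 0]
            b = pos.min() if pos.size else 1.0
        return _kernel_from_distance(d, b, kernel)
    return _kernel_from_distance(d, bandwidth, kernel)


# ---------------------------------------------------------------------------
# local and global least squares

def fit_local(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    error_variance: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted least-squares estimate and standard errors at one focal point.

    ``beta = (X'WX)^{-1} X'W y``; standard errors come from the covariance
    ``sigma^2 C C'`` with ``C = (X'WX)^{-1} X'W``.  ``error_variance`` is the
    model-level residual variance; when absent it is estimated from the
    weighted residuals of this local fit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    XtW = (X * w[:, None]).T
    G = XtW @ X
    try:
        C = np.linalg.solve(G, XtW)
    except np.linalg.LinAlgError as exc:
        raise DegenerateDesignError("weighted design is rank deficient") from exc
    beta = C @ y
    if error_variance is None:
        resid = y - X @ beta
        denom = max(w.sum() - X.shape[1], 1.0)
        error_variance = float((w * resid**2).sum() / denom)
    se = np.sqrt(error_variance * (C**2).sum(axis=1))
    return beta, se


def global_ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Global OLS coefficients and residual sum of squares (the comparator
    model for the spatial-heterogeneity F test)."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def _batch_beta(X: np.ndarray, y: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Local coefficients at every focal point: solve the n weighted
    normal-equation systems in one batched call."""
    G = np.einsum("fn,ni,nj->fij", W, X, X, optimize=True)
    h = np.einsum("fn,ni,n->fi", W, X, y, optimize=True)
    try:
        return np.linalg.solve(G, h[..., None])[..., 0]
    except np.linalg.LinAlgError:
        # rank-deficient local fits (e.g. all-zero covariate inside a narrow
        # kernel): minimum-norm solution per focal point
        out = np.empty_like(h)
        for i in range(G.shape[0]):
            out[i] = np.linalg.lstsq(G[i], h[i], rcond=None)[0]
        return out


# ---------------------------------------------------------------------------
# full fit

def fit_gwr(
    design: GWRDesign,
    kernel: str,
    bandwidth: float,
    adaptive: bool = False,
) -> GWRFit:
    """Fit GWR at every lek and assemble model-level statistics.

    Gaussian: hat_trace = tr(S); effective_params = 2 tr(S) - tr(S'S);
    AICc = n ln(rss/n) + n ln(2 pi) + n (n + tr(S)) / (n - 2 - tr(S));
    pseudo-R^2 = 1 - rss/tss, with the usual caveat that GWR pseudo-R^2
    values are not bounded by [0, 1] across differing responses.
    Binomial: local IRLS logistic fits (max 25 iterations, tolerance 1e-8);
    non-convergent or rank-deficient leks are flagged and excluded from maps
    but do not abort the run.
    """
    if design.family == "binomial":
        return _fit_gwr_binomial(design, kernel, bandwidth, adaptive)
    X, y = design.X, design.y
    n, p = design.n, design.p
    D = cdist(design.coords, design.coords)
    W = _weight_matrix(D, bandwidth, kernel, adaptive)

    G = np.einsum("fn,ni,nj->fij", W, X, X, optimize=True)
    M = np.einsum("fn,ni->fin", W, X, optimize=True)  # (n, p, n): X'W per focal
    beta = np.full((n, p), np.nan)
    S = np.zeros((n, n))
    var_unit = np.full((n, p), np.nan)  # diag(C C') per focal
    flagged: list[int] = []
    try:
        B = np.linalg.solve(G, M)  # (n, p, n): C = (X'WX)^{-1} X'W per focal
        beta = np.einsum("fpn,n->fp", B, y, optimize=True)
        S = np.einsum("fp,fpn->fn", X, B, optimize=True)
        var_unit = (B**2).sum(axis=2)
    except np.linalg.LinAlgError:
        for i in range(n):
            try:
                Ci = np.linalg.solve(G[i], M[i])
                beta[i] = Ci @ y
                S[i] = X[i] @ Ci
                var_unit[i] = (Ci**2).sum(axis=1)
            except np.linalg.LinAlgError:
                flagged.append(i)
                S[i, i] = 1.0  # degenerate focal: interpolate itself

    fitted = S @ y
    resid = y - fitted
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    tr_s = float(np.trace(S))
    tr_sts = float((S**2).sum())
    eff = 2 * tr_s - tr_sts
    dof = n - eff
    sigma2 = rss / dof if dof > 0 else math.nan
    with np.errstate(invalid="ignore"):
        se = np.sqrt(sigma2 * var_unit)
        t = np.where(se > 0, beta / se, 0.0)
    denom = n - 2.0 - tr_s
    aicc = (
        n * math.log(max(rss, 1e-300) / n) + n * math.log(2 * math.pi) + n * (n + tr_s) / denom
        if denom > 0
        else math.inf
    )
    pseudo_r2 = 1.0 - rss / tss if tss > 0 else math.nan
    return GWRFit(
        bandwidth=bandwidth, kernel=kernel, adaptive=adaptive,
        local_beta=beta, local_se=se, local_t=t,
        hat_trace=tr_s, effective_params=eff,
        residuals=resid, fitted=fitted, rss=rss, aicc=aicc,
        pseudo_r2=pseudo_r2, sigma2=sigma2, design=design, flagged=flagged,
    )


def _fit_gwr_binomial(
    design: GWRDesign, kernel: str, bandwidth: float, adaptive: bool,
    max_iter: int = 25, tol: float = 1e-8,
) -> GWRFit:
    X, y = design.X, design.y
    n, p = design.n, design.p
    D = cdist(design.coords, design.coords)
    W = _weight_matrix(D, bandwidth, kernel, adaptive)
    beta = np.full((n, p), np.nan)
    se = np.full((n, p), np.nan)
    mu_self = np.full(n, np.nan)
    lev = np.zeros(n)
    flagged: list[int] = []
    for i in range(n):
        wk = W[i]
        b = np.zeros(p)
        converged = False
        for _ in range(max_iter):
            eta = X @ b
            mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
            v = np.clip(mu * (1 - mu), 1e-10, None) * wk
            z = eta + (y - mu) / np.clip(mu * (1 - mu), 1e-10, None)
            G = (X * v[:, None]).T @ X
            try:
                b_new = np.linalg.solve(G, (X * v[:, None]).T @ z)
            except np.linalg.LinAlgError:
                break
            step = float(np.max(np.abs(b_new - b)))
            b = b_new
            if step < tol:
                converged = True
                break
        if not converged:
            flagged.append(i)
        beta[i] = b
        eta = X @ b
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        v = np.clip(mu * (1 - mu), 1e-10, None) * wk
        G = (X * v[:, None]).T @ X
        try:
            Ginv = np.linalg.inv(G)
            se[i] = np.sqrt(np.diag(Ginv))
            lev[i] = float(X[i] @ Ginv @ X[i]) * v[i]
        except np.linalg.LinAlgError:
            flagged.append(i)
        mu_self[i] = mu[i]
    mu_self = np.clip(mu_self, 1e-10, 1 - 1e-10)
    deviance = -2.0 * float(np.sum(y * np.log(mu_self) + (1 - y) * np.log(1 - mu_self)))
    pbar = np.clip(y.mean(), 1e-10, 1 - 1e-10)
    null_dev = -2.0 * float(np.sum(y * np.log(pbar) + (1 - y) * np.log(1 - pbar)))
    tr_s = float(lev.sum())
    resid = y - mu_self
    rss = float(resid @ resid)
    k = tr_s
    aicc = deviance + 2 * k + (2 * k * (k + 1) / (n - k - 1) if n - k - 1 > 0 else math.inf)
    with np.errstate(invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    return GWRFit(
        bandwidth=bandwidth, kernel=kernel, adaptive=adaptive,
        local_beta=beta, local_se=se, local_t=t,
        hat_trace=tr_s, effective_params=tr_s,
        residuals=resid, fitted=mu_self, rss=rss, aicc=aicc,
        pseudo_r2=1.0 - deviance / null_dev if null_dev > 0 else math.nan,
        sigma2=math.nan, design=design, flagged=sorted(set(flagged)),
    )


# ---------------------------------------------------------------------------
# bandwidth selection

_GOLDEN = (math.sqrt(5) - 1) / 2


def select_bandwidth(
    design: GWRDesign,
    kernel: str = "bisquare",
    mode: str = "adaptive",
    n_coarse: int = 12,
) -> float:
    """Bandwidth minimising the fit AICc.

    A coarse scan brackets the minimum, then golden-section search refines
    it.  Fixed mode searches metres in [min positive pairwise distance,
    extent diagonal]; adaptive mode searches neighbour counts in
    [p + 2, n].  Deterministic.  If the profile is not unimodal the coarse
    grid minimum is returned with a warning.
    """
    n, p = design.n, design.p
    if n < 3 * p:
        raise ContractError(f"need n >= 3p (n={n}, p={p}) for bandwidth selection")
    D = cdist(design.coords, design.coords)
    adaptive = mode == "adaptive"
    if adaptive:
        lo, hi = float(p + 2), float(n)
        snap = lambda b: float(int(round(b)))
    else:
        pos = D[D > 0]
        if pos.size == 0:
            raise DegenerateDesignError("all coordinates coincide")
        span_x = design.coords[:, 0].max() - design.coords[:, 0].min()
        span_y = design.coords[:, 1].max() - design.coords[:, 1].min()
        lo, hi = float(pos.min()), float(math.hypot(span_x, span_y))
        snap = float
    if hi <= lo:
        return snap(hi)

    cache: dict[float, float] = {}

    def objective(b: float) -> float:
        b = snap(max(lo, min(hi, b)))
        if b not in cache:
            fit = fit_gwr(design, kernel, b, adaptive=adaptive)
            # a bandwidth so local that some lek is not estimable is not a
            # candidate
            cache[b] = math.inf if fit.flagged else fit.aicc
        return cache[b]

    grid = np.linspace(lo, hi, n_coarse)
    scores = [objective(g) for g in grid]
    i_min = int(np.argmin(scores))
    a = grid[max(i_min - 1, 0)]
    c = grid[min(i_min + 1, len(grid) - 1)]
    # golden-section refinement inside the bracket
    x1 = c - _GOLDEN * (c - a)
    x2 = a + _GOLDEN * (c - a)
    f1, f2 = objective(x1), objective(x2)
    while abs(c - a) > (1.0 if adaptive else max(1e-3 * (hi - lo), 1e-9)):
        if f1 <= f2:
            c, x2, f2 = x2, x1, f1
            x1 = c - _GOLDEN * (c - a)
            f1 = objective(x1)
        else:
            a, x1, f1 = x1, x2, f2
            x2 = a + _GOLDEN * (c - a)
            f2 = objective(x2)
    best = min(cache, key=lambda b: (cache[b], b))
    grid_best = snap(grid[i_min])
    if cache[grid_best] < cache[best] - 1e-9:
        warnings.warn("AICc profile not unimodal; returning coarse-grid minimum", stacklevel=2)
        return grid_best
    return best


# ---------------------------------------------------------------------------
# inference

def anova_vs_global(fit: GWRFit, global_rss: float, n: int, p: int) -> AnovaResult:
    """Approximate F test of the GWR improvement over the global model:

    F = [(RSS_global - RSS_gwr) / (eff - p)] / [RSS_gwr / (n - eff)].
    Undefined (reported as such, not raised) when eff <= p.
    """
    eff = fit.effective_params
    df1 = eff - p
    df2 = n - eff
    if df1 <= 0 or df2 <= 0:
        return AnovaResult(math.nan, math.nan, df1, df2, defined=False)
    F = ((global_rss - fit.rss) / df1) / (fit.rss / df2)
    F = max(F, 0.0)
    p_value = float(stats.f.sf(F, df1, df2))
    return AnovaResult(float(F), p_value, df1, df2)


def monte_carlo_nonstationarity(
    design: GWRDesign,
    kernel: str,
    bandwidth: float,
    n_permutations: int,
    seed: int,
    adaptive: bool = False,
) -> MonteCarloResult:
    """Permutation test of spatial nonstationarity per covariate.

    The observed statistic is the variance over leks of each local
    coefficient.  Each permutation shuffles the coordinate rows against the
    fixed (y, X) rows, refits GWR with the *same* bandwidth, and recomputes
    the statistic.  ``p = (1 + #{perm >= obs}) / (1 + n_permutations)``.
    """
    if n_permutations < 19:
        raise ContractError("need at least 19 permutations for a 0.05-level test")
    X, y = design.X, design.y
    D = cdist(design.coords, design.coords)
    W = _weight_matrix(D, bandwidth, kernel, adaptive)
    observed = np.var(_batch_beta(X, y, W), axis=0, ddof=1)
    rng = np.random.default_rng(seed)
    permuted = np.empty((n_permutations, design.p))
    for m in range(n_permutations):
        idx = rng.permutation(design.n)
        Wp = _weight_matrix(D[np.ix_(idx, idx)], bandwidth, kernel, adaptive)
        permuted[m] = np.var(_batch_beta(X, y, Wp), axis=0, ddof=1)
    p_values = (1.0 + (permuted >= observed).sum(axis=0)) / (1.0 + n_permutations)
    return MonteCarloResult(
        covariate_names=list(design.covariate_names),
        observed=observed, permuted=permuted, p_values=p_values,
        seed=seed, n_permutations=n_permutations,
    )
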