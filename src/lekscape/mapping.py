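"""Significance mapping: select leks with significant local responses,
interpolate their response rates into continuous surfaces with inverse
distance weighting, and summarise regions.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .errors import ContractError
from .gwr import GWRFit
from .types import Surface

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of an interpolation grid (lower-left origin, metres)."""

    origin: tuple[float, float]
    cell_size: float
    nrows: int
    ncols: int

    @classmethod
    def covering(cls, coords: np.ndarray, cell_size: float, pad: float = 0.0) -> "GridSpec":
        """Smallest grid of ``cell_size`` covering ``coords`` padded by
        ``pad`` metres on every side."""
        coords = np.asarray(coords, dtype=float)
        x0 = coords[:, 0].min() - pad
        y0 = coords[:, 1].min() - pad
        x1 = coords[:, 0].max() + pad
        y1 = coords[:, 1].max() + pad
        ncols = max(1, int(math.ceil((x1 - x0) / cell_size)))
        nrows = max(1, int(math.ceil((y1 - y0) / cell_size)))
        return cls((x0, y0), cell_size, nrows, ncols)


@dataclass
class RegionSummary:
    """Mean pad density, mean attendance-change rate, and lek count of a
    mapped region.  ``n == 0`` marks an explicitly empty summary."""

    mean_density: Optional[float]
    mean_response: Optional[float]
    n: int


def significant_leks(
    fit: GWRFit,
    covariate: str,
    alpha: float,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Leks whose local t exceeds the two-sided critical value at ``alpha``.

    Degrees of freedom are ``n - effective_params``.  Per-lek tests are
    uncorrected by default, matching the per-lek t-test usage of the
    original workflow; ``bh_correction`` applies Benjamini-Hochberg across
    leks instead.
    """
    names = fit.design.covariate_names
    if covariate not in names:
        raise ContractError(f"covariate {covariate!r} not in fit ({names})")
    j = names.index(covariate)
    df = fit.residual_df
    tvals = fit.local_t[:, j]
    ok = np.isfinite(tvals)
    ok[fit.flagged] = False
    if bh_correction:
        from statsmodels.stats.multitest import multipletests

        pvals = 2 * stats.t.sf(np.abs(tvals), df)
        keep = np.zeros_like(ok)
        if ok.any():
            rej, *_ = multipletests(pvals[ok], alpha=alpha, method="fdr_bh")
            keep[np.flatnonzero(ok)] = rej
    else:
        crit = stats.t.ppf(1 - alpha / 2, df)
        keep = ok & (np.abs(tvals) > crit)
    idx = np.flatnonzero(keep)
    ids = fit.design.lek_ids or [str(i) for i in range(fit.n)]
    return pd.DataFrame(
        {
            "lek_id": [ids[i] for i in idx],
            "x": fit.design.coords[idx, 0],
            "y": fit.design.coords[idx, 1],
            "local_beta": fit.local_beta[idx, j],
            "local_t": tvals[idx],
        }
    )


def idw_interpolate(
    points: np.ndarray,
    values: Sequence[float],
    grid_spec: GridSpec,
    power: float = 2.0,
) -> Surface:
    """Inverse-distance-weighted surface of ``values`` at ``points``.

    Cell value = sum(v_i d_i^-power) / sum(d_i^-power); a cell whose centre
    coincides with a sample point takes that point's value exactly.  All
    interpolated values lie within [min, max] of the samples.  An empty
    point set yields an all-no-data surface.
    """
    if power <= 0:
        raise ContractError("IDW power must be positive")
    values = np.asarray(values, dtype=float)
    surf = Surface(
        origin=grid_spec.origin, cell_size=grid_spec.cell_size,
        nrows=grid_spec.nrows, ncols=grid_spec.ncols,
        values=np.full((grid_spec.nrows, grid_spec.ncols), NODATA),
        nodata=NODATA,
    )
    if values.size == 0:
        return surf
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    Xc, Yc = surf.cell_centers()
    cells = np.column_stack([Xc.ravel(), Yc.ravel()])
    d = cdist(cells, points)
    out = np.empty(cells.shape[0])
    exact = d == 0
    hit = exact.any(axis=1)
    out[hit] = values[np.argmax(exact[hit], axis=1)]
    with np.errstate(divide="ignore"):
        wts = d[~hit] ** (-power)
    out[~hit] = (wts * values).sum(axis=1) / wts.sum(axis=1)
    surf.values = out.reshape(grid_spec.nrows, grid_spec.ncols)
    return surf


def region_summary(
    densities: Sequence[float], responses: Sequence[float]
) -> RegionSummary:
    """Arithmetic means of density and response rate over a lek subset."""
    densities = np.asarray(densities, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if densities.size != responses.size:
        raise ContractError("densities and responses must be aligned")
    if densities.size == 0:
        return RegionSummary(mean_density=None, mean_response=None, n=0)
    return RegionSummary(
        mean_density=float(densities.mean()),
        mean_response=float(responses.mean()),
        n=int(densities.size),
    )


def opposing_response_pairs(
    lek_ids: Sequence[str],
    densities: Sequence[float],
    trends: Sequence[float],
    tolerance: float = 0.05,
) -> list[tuple[str, str]]:
    """Pairs of leks with (near-)identical pad density but opposite-signed
    attendance trends.

    Each increasing lek (trend > 0) is greedily matched to the unused
    decreasing lek (trend < 0) whose density is nearest, provided the
    densities agree within relative ``tolerance``
    (|d1 - d2| <= tolerance * max(|d1|, |d2|); equal densities always
    match).  Each lek appears in at most one pair.
    """
    if tolerance < 0:
        raise ContractError("tolerance must be non-negative")
    densities = np.asarray(densities, dtype=float)
    trends = np.asarray(trends, dtype=float)
    inc = [i for i in range(len(lek_ids)) if trends[i] > 0]
    dec = [i for i in range(len(lek_ids)) if trends[i] < 0]
    pairs: list[tuple[str, str]] = []
    used: set[int] = set()
    for i in sorted(inc, key=lambda i: densities[i]):
        best, best_gap = None, math.inf
        for j in dec:
            if j in used:
                continue
            gap = abs(densities[i] - densities[j])
            limit = tolerance * max(abs(densities[i]), abs(densities[j]))
            if gap <= limit and gap < best_gap:
                best, best_gap = j, gap
        if best is not None:
            used.add(best)
            pairs.append((str(lek_ids[i]), str(lek_ids[best])))
    return pairs


def write_asc(surface: Surface, path) -> None:
    """Write a surface as an ESRI ASCII grid (rows written north to south)."""
    vals = np.asarray(surface.values, dtype=float)
    lines = [
        f"ncols {surface.ncols}",
        f"nrows {surface.nrows}",
        f"xllcorner {surface.origin[0]}",
        f"yllcorner {surface.origin[1]}",
        f"cellsize {surface.cell_size}",
        f"NODATA_value {surface.nodata}",
    ]
    for row in vals[::-1]:
        lines.append(" ".join(f"{v:.6g}" for v in row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_asc(path) -> Surface:
    """Read an ESRI ASCII grid written by :func:`write_asc`."""
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    vals = np.atleast_2d(vals)[::-1]
    return Surface(
        origin=(header["xllcorner"], header["yllcorner"]),
        cell_size=header["cellsize"],
        nrows=int(header["nrows"]), ncols=int(header["ncols"]),
        values=vals, nodata=header["nodata_value"],
    )
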