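"""Active-pad filtering and roving-window point density around leks.

Density is the literal count of active pads on the *closed* disc of a given
radius around a lek, divided by the full disc area (pads/km^2).  No edge
correction is applied when a disc crosses the study extent, matching standard
GIS point-density behaviour.
"""
from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ConfigurationError
from .types import AnalysisConfig, DensityCovariate, LekSeries, PadRecord

#: Classification codes marking pads that were permitted but never drilled.
NEVER_DRILLED_CLASSES = frozenset({"AP"})
#: Status codes marking pads that ceased activity (dry hole, dormant); such a
#: pad accompanied by a cessation date never counts as producing.
CEASED_STATUSES = frozenset({"DH", "DR"})


def filter_active_pads(pads: Sequence[PadRecord], year: int) -> list[PadRecord]:
    """Pads physically present and producing in ``year``.

    A pad is active when its interval covers the year
    (``start_year <= year`` and ``end_year`` absent or ``>= year``), except
    that permit-only pads (class in :data:`NEVER_DRILLED_CLASSES` with no
    start year) and ceased pads (status in :data:`CEASED_STATUSES` with a
    recorded end date) are never active.  A missing start year on an
    ordinary pad means "present since before records" and is kept.
    """
    out = []
    for p in pads:
        if p.class_code in NEVER_DRILLED_CLASSES and p.start_year is None:
            continue
        if p.status_code in CEASED_STATUSES and p.end_year is not None:
            continue
        if p.start_year is not None and p.start_year > year:
            continue
        if p.end_year is not None and p.end_year < year:
            continue
        out.append(p)
    return out


def count_to_density(n_pads: int, radius_km: float) -> float:
    """Pads-per-km^2 of ``n_pads`` on a disc of ``radius_km``."""
    if radius_km <= 0:
        raise ConfigurationError("radius_km must be positive")
    return n_pads / (math.pi * radius_km**2)


def density_to_count(density: float, radius_km: float) -> float:
    """Inverse of :func:`count_to_density`; real-valued pad count."""
    if radius_km <= 0:
        raise ConfigurationError("radius_km must be positive")
    return density * math.pi * radius_km**2


def roving_density(
    pads: Sequence[PadRecord],
    centers: Sequence[LekSeries],
    radius_km: float,
    year: int,
) -> list[DensityCovariate]:
    """Active-pad density on the closed disc of ``radius_km`` around each lek.

    Pads at exactly the radius are included (closed-disc convention).
    """
    if radius_km <= 0:
        raise ConfigurationError("radius_km must be positive")
    active = filter_active_pads(pads, year)
    area = math.pi * radius_km**2
    if not active:
        return [
            DensityCovariate(lek.lek_id, radius_km, year, 0.0) for lek in centers
        ]
    tree = cKDTree(np.array([[p.x, p.y] for p in active]))
    pts = np.array([[lek.x, lek.y] for lek in centers])
    counts = tree.query_ball_point(pts, r=radius_km * 1000.0, return_length=True)
    return [
        DensityCovariate(lek.lek_id, radius_km, year, int(c) / area)
        for lek, c in zip(centers, counts)
    ]


def density_matrix(
    leks: Sequence[LekSeries],
    pads: Sequence[PadRecord],
    config: AnalysisConfig,
    window_start_year: int,
    history_start_year: Optional[int] = None,
) -> pd.DataFrame:
    """Covariate table: one row per lek, one column per (radius, lag).

    Column ``(r, l)`` holds the density at radius ``r`` evaluated in
    reference year ``window_start_year - l``.  Column order is deterministic:
    radius-major, lag-minor, in config order.  ``history_start_year``, when
    given, is the first year the pad table is known to cover; reference
    years before it raise :class:`ConfigurationError`.
    """
    max_lag = max(config.lag_years)
    if history_start_year is not None and window_start_year - max_lag < history_start_year:
        raise ConfigurationError(
            f"pad history starts {history_start_year}; lag {max_lag} needs "
            f"year {window_start_year - max_lag}"
        )
    cols = {}
    for r in config.radii_km:
        for lag in config.lag_years:
            ref = window_start_year - lag
            dens = roving_density(pads, leks, r, ref)
            cols[(r, lag)] = [d.value for d in dens]
    idx = pd.Index([lek.lek_id for lek in leks], name="lek_id")
    df = pd.DataFrame(cols, index=idx)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["radius_km", "lag_years"])
    return df


def density_table_long(matrix: pd.DataFrame, window_start_year: int) -> pd.DataFrame:
    """Long-form view of :func:`density_matrix` for CSV export."""
    rows = []
    for (r, lag) in matrix.columns:
        for lek_id, value in matrix[(r, lag)].items():
            rows.append(
                {"lek_id": lek_id, "radius_km": r, "lag_years": lag,
                 "reference_year": window_start_year - lag, "density": value}
            )
    return pd.DataFrame(rows)
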