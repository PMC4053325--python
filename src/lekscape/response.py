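"""Functional response of attendance change to pad density.

For each (radius, lag) region a straight line of attendance change
(males/lek/year) on pad density (pads/km^2) summarises the dose-response;
the line is then used to forecast the mean decline at current densities and
to solve for the largest density whose predicted change still clears a
floor — the sustainable development density.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .density import density_to_count
from .errors import ContractError, DegenerateDesignError, UnboundedThresholdError
from .types import ResponseLine

Key = tuple[float, int]  # (radius_km, lag_years)


@dataclass(frozen=True)
class ForecastReport:
    """Aggregate forecast plus the per-line contributions it was built from."""

    per_line: dict[Key, float]
    aggregate: float
    aggregation: str = "mean"


@dataclass(frozen=True)
class ThresholdReport:
    """Sustainable density in both pads/km^2 and (real-valued) pad count."""

    radius_km: float
    lag_years: int
    floor: float
    density: float
    pad_count: float


def fit_response_line(
    densities: Sequence[float],
    changes: Sequence[float],
    radius_km: float,
    lag_years: int,
) -> ResponseLine:
    """OLS line of attendance change on pad density for one region."""
    d = np.asarray(densities, dtype=float)
    c = np.asarray(changes, dtype=float)
    if d.size != c.size:
        raise ContractError("densities and changes must be aligned")
    if d.size < 2:
        raise ContractError("need at least 2 leks to fit a response line")
    if np.var(d) == 0:
        raise DegenerateDesignError("zero density variance: slope undefined")
    slope, intercept = np.polyfit(d, c, 1)
    return ResponseLine(
        radius_km=radius_km, lag_years=lag_years,
        slope=float(slope), intercept=float(intercept),
    )


def predict_change(line: ResponseLine, density: float) -> float:
    """Predicted attendance change (males/lek/year) at ``density``."""
    if density < 0:
        raise ContractError("density must be non-negative")
    return line.slope * density + line.intercept


def forecast_mean_decline(
    lines: Mapping[Key, ResponseLine],
    current_densities: Mapping[Key, float],
) -> ForecastReport:
    """Combine per-region predictions at current densities.

    The aggregate is the arithmetic mean of the per-line predictions; the
    per-line vector is always reported so any alternative aggregation can be
    recomputed.
    """
    if set(lines) != set(current_densities):
        raise ContractError(
            f"line keys {sorted(lines)} do not match density keys "
            f"{sorted(current_densities)}"
        )
    if not lines:
        raise ContractError("no response lines to forecast from")
    per_line = {k: predict_change(lines[k], current_densities[k]) for k in sorted(lines)}
    return ForecastReport(per_line=per_line, aggregate=float(np.mean(list(per_line.values()))))


def sustainable_density(line: ResponseLine, floor: float = 0.0) -> ThresholdReport:
    """Largest density whose predicted attendance change is still >= ``floor``.

    Defined only for declining responses (slope < 0); a flat or increasing
    line has no finite threshold and raises
    :class:`UnboundedThresholdError`.  Returns 0 when even an undeveloped
    landscape (density 0) violates the floor.  The pad-count reading uses
    the literal count = density * pi * r^2 conversion.
    """
    if line.slope >= 0:
        raise UnboundedThresholdError(
            f"slope {line.slope} is not declining; sustainable density unbounded"
        )
    d = (floor - line.intercept) / line.slope
    d = max(0.0, d)
    return ThresholdReport(
        radius_km=line.radius_km, lag_years=line.lag_years, floor=floor,
        density=d, pad_count=density_to_count(d, line.radius_km),
    )


def percent_change(total_before: float, total_after: float) -> float:
    """Signed percent change between two totals (negative = decline)."""
    if total_before <= 0:
        raise ContractError("baseline total must be positive")
    return 100.0 * (total_after - total_before) / total_before


def fold_change(a: float, b: float) -> float:
    """How many times larger ``a`` is than ``b``."""
    if b == 0:
        raise ContractError("fold change undefined for zero denominator")
    return a / b


def surveys_per_lek(total_surveys: int, n_leks: int) -> float:
    """Mean number of counts per lek in a survey database."""
    if n_leks <= 0:
        raise ContractError("lek count must be positive")
    return total_surveys / n_leks
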