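"""Core domain types.

All coordinates are already-projected planar metres; the package performs no
geodesy.  A *lek* is a communal courtship display site; its yearly record is
the peak number of males counted there.  A *pad* is a ground installation
supporting one or more oil/gas wells, with an activity interval in years.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

from .errors import ValidationError

ACTIVITY_STATES = ("active", "inactive", "unknown")


@dataclass(frozen=True)
class LekYear:
    """One surveyed year at one lek."""

    males: float  # peak male count; non-negative, integer-valued for real surveys
    surveyed: bool = True
    activity: str = "active"  # one of ACTIVITY_STATES

    def __post_init__(self) -> None:
        if self.surveyed and (self.males < 0 or not math.isfinite(self.males)):
            raise ValidationError(f"peak male count must be finite and >= 0, got {self.males}")
        if self.activity not in ACTIVITY_STATES:
            raise ValidationError(f"activity must be one of {ACTIVITY_STATES}, got {self.activity!r}")


@dataclass
class LekSeries:
    """A lek's location plus its per-year survey records.

    Counts exist only for surveyed years; unsurveyed years are simply absent
    from ``records``.  A surveyed-inactive year is an observed zero.
    """

    lek_id: str
    x: float
    y: float
    records: dict[int, LekYear] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(f"lek {self.lek_id}: coordinates must be finite")
        self.records = dict(sorted(self.records.items()))

    @property
    def years(self) -> list[int]:
        return sorted(self.records)

    @property
    def surveyed_years(self) -> list[int]:
        return [yr for yr, rec in self.records.items() if rec.surveyed]

    def counts(self) -> tuple[list[int], list[float]]:
        """(years, peak male counts) over surveyed years, year-ascending."""
        yrs = self.surveyed_years
        return yrs, [self.records[yr].males for yr in yrs]

    def occupied(self, final_year: int) -> bool:
        """Management-status flag: males displayed at least once in the most
        recent 10 years ending at ``final_year``.  Derived only; never a model
        response."""
        lo = final_year - 9
        return any(
            lo <= yr <= final_year and rec.surveyed and rec.males > 0
            for yr, rec in self.records.items()
        )

    def with_records(self, records: dict[int, LekYear]) -> "LekSeries":
        return replace(self, records=records)


@dataclass(frozen=True)
class PadRecord:
    """One well pad: location, agency classification/status codes, and the
    activity interval in whole years (either bound may be absent)."""

    pad_id: str
    x: float
    y: float
    class_code: str = ""
    status_code: str = ""
    start_year: Optional[int] = None
    end_year: Optional[int] = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(f"pad {self.pad_id}: coordinates must be finite")
        if (
            self.start_year is not None
            and self.end_year is not None
            and self.end_year < self.start_year
        ):
            raise ValidationError(
                f"pad {self.pad_id}: end_year {self.end_year} < start_year {self.start_year}"
            )


@dataclass
class AnalysisConfig:
    """Pipeline settings.

    Defaults reproduce the study design: pad densities within 0.5, 1, 2, 5
    and 10 km of each lek, lagged 1, 3, 5 and 10 years before the trend
    window, and attendance trends over the most recent 3, 5 and 10 years.
    """

    radii_km: tuple[float, ...] = (0.5, 1.0, 2.0, 5.0, 10.0)
    lag_years: tuple[int, ...] = (1, 3, 5, 10)
    trend_windows: tuple[int, ...] = (3, 5, 10)
    kernel: str = "bisquare"  # {gaussian, bisquare}
    bandwidth_mode: str = "adaptive"  # {fixed, adaptive}
    n_permutations: int = 99
    alpha: float = 0.05
    seed: int = 0
    idw_power: float = 2.0
    grid_cell_m: float = 1000.0
    lowess_span_grid: tuple[float, ...] = (0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
    lowess_fit_scale: str = "logit"  # {logit, count}

    def __post_init__(self) -> None:
        if not self.radii_km or any(r <= 0 for r in self.radii_km):
            raise ValidationError("radii_km must be positive")
        if any(l < 0 for l in self.lag_years):
            raise ValidationError("lag_years must be non-negative")
        if any(w < 2 for w in self.trend_windows):
            raise ValidationError("trend_windows must each span >= 2 years")
        if self.kernel not in ("gaussian", "bisquare"):
            raise ValidationError(f"unknown kernel {self.kernel!r}")
        if self.bandwidth_mode not in ("fixed", "adaptive"):
            raise ValidationError(f"unknown bandwidth_mode {self.bandwidth_mode!r}")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be positive")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.idw_power <= 0:
            raise ValidationError("idw_power must be positive")
        if self.grid_cell_m <= 0:
            raise ValidationError("grid_cell_m must be positive")
        if self.lowess_fit_scale not in ("logit", "count"):
            raise ValidationError(f"unknown lowess_fit_scale {self.lowess_fit_scale!r}")


@dataclass(frozen=True)
class DensityCovariate:
    """Active-pad density (pads/km^2) on a closed disc around one lek, for one
    radius and one reference year."""

    lek_id: str
    radius_km: float
    reference_year: int
    value: float

    def __post_init__(self) -> None:
        if self.radius_km <= 0:
            raise ValidationError("radius_km must be positive")
        if self.value < 0:
            raise ValidationError("density must be non-negative")


@dataclass(frozen=True)
class TrendResponse:
    """One response value for one lek.

    ``kind`` is one of trend3/trend5/trend10 (attendance slope in
    males/lek/year over the window), adjusted_final_count (smoothed count in
    the final year, in males), or binary (1 increasing, 0 decreasing).
    """

    lek_id: str
    kind: str
    value: float
    window_start_year: int
    window_end_year: int

    def __post_init__(self) -> None:
        if self.kind == "binary" and self.value not in (0.0, 1.0):
            raise ValidationError("binary response must be 0 or 1")


@dataclass(frozen=True)
class ResponseLine:
    """Fitted line of attendance change (males/lek/year) on pad density
    (pads/km^2) for one radius x lag combination."""

    radius_km: float
    lag_years: int
    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.slope) and math.isfinite(self.intercept)):
            raise ValidationError("response line coefficients must be finite")


@dataclass
class Surface:
    """A regular grid of reals with a no-data sentinel.

    ``origin`` is the lower-left corner; ``values[0, 0]`` is the lower-left
    cell, rows increase northward.
    """

    origin: tuple[float, float]
    cell_size: float
    nrows: int
    ncols: int
    values: "object"  # numpy array (nrows, ncols)
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.nrows <= 0 or self.ncols <= 0 or self.cell_size <= 0:
            raise ValidationError("surface dimensions and cell size must be positive")

    def cell_centers(self):
        """(X, Y) arrays of shape (nrows, ncols) with cell-centre coordinates."""
        import numpy as np

        x0, y0 = self.origin
        xs = x0 + (np.arange(self.ncols) + 0.5) * self.cell_size
        ys = y0 + (np.arange(self.nrows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)
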