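"""Readers, writers, eligibility filtering and configuration loading.

File formats are deliberately plain: comma-separated UTF-8 CSV with a header
row and '.' decimals, GeoJSON for per-lek point results, and a flat TOML file
mirroring :class:`~lekscape.types.AnalysisConfig`.
"""
from __future__ import annotations

import json
import tomllib
from dataclasses import fields as dc_fields
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import ConfigurationError, FormatError, ValidationError
from .types import ACTIVITY_STATES, AnalysisConfig, LekSeries, LekYear, PadRecord

LEK_COLUMNS = ("lek_id", "x", "y", "year", "males", "status")
PAD_COLUMNS = ("pad_id", "x", "y", "class", "status", "start_year", "end_year")


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_lek_table(path) -> list[LekSeries]:
    """Read a lek survey table.

    Each row is one survey of one lek in one year; unsurveyed lek-years have
    no row.  Malformed rows raise :class:`ValidationError` naming the
    offending row (1-based, excluding the header).
    """
    df = pd.read_csv(path, dtype={"lek_id": str, "status": str},
                     float_precision="round_trip")
    _require_columns(df, LEK_COLUMNS, path)

    leks: dict[str, LekSeries] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            year = int(row.year)
            males = float(row.males)
            if males < 0:
                raise ValidationError(f"negative male count {males}")
            status = str(row.status).strip().lower()
            if status not in ACTIVITY_STATES:
                raise ValidationError(f"unknown status {row.status!r}")
            rec = LekYear(males=males, surveyed=True, activity=status)
            lek_id = str(row.lek_id)
            if lek_id not in leks:
                leks[lek_id] = LekSeries(lek_id=lek_id, x=float(row.x), y=float(row.y))
            if year in leks[lek_id].records:
                raise ValidationError(f"duplicate year {year} for lek {lek_id}")
            leks[lek_id].records[year] = rec
        except (TypeError, ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    out = list(leks.values())
    for lek in out:
        lek.records = dict(sorted(lek.records.items()))
    return out


def write_lek_table(leks: Iterable[LekSeries], path) -> None:
    rows = []
    for lek in leks:
        for year, rec in sorted(lek.records.items()):
            if not rec.surveyed:
                continue
            rows.append(
                {"lek_id": lek.lek_id, "x": lek.x, "y": lek.y, "year": year,
                 "males": rec.males, "status": rec.activity}
            )
    pd.DataFrame(rows, columns=list(LEK_COLUMNS)).to_csv(
        path, index=False, float_format="%.17g"
    )


def _opt_year(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or str(value).strip() == "":
        return None
    return int(float(value))


def read_pad_table(path) -> list[PadRecord]:
    """Read a well-pad table; empty start/end fields map to absent bounds."""
    df = pd.read_csv(path, dtype={"pad_id": str, "class": str, "status": str},
                     float_precision="round_trip")
    _require_columns(df, PAD_COLUMNS, path)
    pads = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        try:
            pads.append(
                PadRecord(
                    pad_id=str(row["pad_id"]),
                    x=float(row["x"]),
                    y=float(row["y"]),
                    class_code="" if pd.isna(row["class"]) else str(row["class"]),
                    status_code="" if pd.isna(row["status"]) else str(row["status"]),
                    start_year=_opt_year(row["start_year"]),
                    end_year=_opt_year(row["end_year"]),
                )
            )
        except (TypeError, ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return pads


def write_pad_table(pads: Iterable[PadRecord], path) -> None:
    rows = [
        {"pad_id": p.pad_id, "x": p.x, "y": p.y, "class": p.class_code,
         "status": p.status_code,
         "start_year": "" if p.start_year is None else p.start_year,
         "end_year": "" if p.end_year is None else p.end_year}
        for p in pads
    ]
    pd.DataFrame(rows, columns=list(PAD_COLUMNS)).to_csv(
        path, index=False, float_format="%.17g"
    )


def filter_eligible_leks(
    leks: Sequence[LekSeries],
    final_year: int,
    data_start_year: Optional[int] = None,
) -> list[LekSeries]:
    """Keep leks with enough survey coverage to fit 3-, 5- and 10-year trends.

    A lek is retained only if it was surveyed (i) in every one of the last 3
    years ending at ``final_year``, (ii) in at least 4 of the last 5 years,
    and (iii) in at least 6 of the last 10 years including the first year of
    that 10-year window.  Idempotent; output is a subset of input.

    ``data_start_year``, when given, declares the first year the survey
    database covers at all; a 10-year window reaching before it is a
    configuration error (individual leks whose own records merely begin
    later are simply rejected).
    """
    window_start = final_year - 9
    if data_start_year is not None and window_start < data_start_year:
        raise ConfigurationError(
            f"10-year window starts {window_start}, before first database "
            f"year {data_start_year}"
        )

    kept = []
    for lek in leks:
        surveyed = set(lek.surveyed_years)
        last3 = all(yr in surveyed for yr in range(final_year - 2, final_year + 1))
        last5 = sum(yr in surveyed for yr in range(final_year - 4, final_year + 1)) >= 4
        last10 = (
            sum(yr in surveyed for yr in range(window_start, final_year + 1)) >= 6
            and window_start in surveyed
        )
        if last3 and last5 and last10:
            kept.append(lek)
    return kept


def write_geojson_points(records: Iterable[Mapping], path) -> None:
    """Write per-lek result rows (mappings with 'x' and 'y' keys) as GeoJSON
    Points; all remaining keys become feature properties."""
    features = []
    for rec in records:
        props = {k: v for k, v in rec.items() if k not in ("x", "y")}
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [rec["x"], rec["y"]]},
                "properties": props,
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


def load_config(path) -> AnalysisConfig:
    """Load an AnalysisConfig from a flat TOML file; unknown keys rejected."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    known = {f.name for f in dc_fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"{path}: unknown config key(s) {sorted(unknown)}")
    listy = {"radii_km", "lag_years", "trend_windows", "lowess_span_grid"}
    kwargs = {k: tuple(v) if k in listy else v for k, v in raw.items()}
    return AnalysisConfig(**kwargs)
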