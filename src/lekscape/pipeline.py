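"""End-to-end orchestration: simulate (or load) a study system, build lagged
density covariates, construct trend responses, fit GWR per response, test
nonstationarity, map significant responses, and fit functional-response
thresholds.

The default simulated study conditions emulate the Wyoming system at
desk scale: a 100 x 100 km extent, two decades of pad accumulation growing
6.6%/year (compounding to ~3.6-fold), a decade of annual lek surveys, lek
baseline attendance around 25 males, 6-year periodicity of amplitude 5, and
a step coefficient field (strongly negative west, zero east) on the 2-km
1-year-lag density covariate.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import core_io, density, gwr, mapping, response, synthetic, trend
from .errors import ContractError
from .types import AnalysisConfig, LekSeries, PadRecord

DEFAULT_EXTENT = (0.0, 0.0, 100_000.0, 100_000.0)
DEFAULT_DESIGN_KEYS = ((1.0, 1), (2.0, 1), (10.0, 3))


@dataclass
class StudySystem:
    """A simulated landscape plus its generating truth."""

    leks: list[LekSeries]
    pads: list[PadRecord]
    truth: synthetic.SimulationTruth
    extent: tuple[float, float, float, float]
    count_years: tuple[int, ...]


@dataclass
class PipelineResult:
    config: AnalysisConfig
    final_year: int
    eligible: list[LekSeries]
    responses: pd.DataFrame  # lek_id x kind wide table of response values
    densities: pd.DataFrame  # lek_id x (radius, lag)
    fits: dict[str, "gwr.GWRFit"]
    best_kind: str
    anova: "gwr.AnovaResult"
    monte_carlo: "gwr.MonteCarloResult"
    significant: dict[str, pd.DataFrame]
    surfaces: dict[str, "object"]
    region_summaries: dict[str, mapping.RegionSummary]
    lines: dict[tuple[float, int], "object"]
    thresholds: dict[tuple[float, int], "object"]
    forecast: Optional[response.ForecastReport]
    opposing_pairs: list[tuple[str, str]]
    summary: dict = field(default_factory=dict)


def simulate_study(
    config: AnalysisConfig,
    n_leks: int = 200,
    extent=DEFAULT_EXTENT,
    pad_years: Optional[Sequence[int]] = None,
    count_years: Optional[Sequence[int]] = None,
    base_intensity: float = 0.004,
    growth: float = synthetic.DEFAULT_GROWTH,
    clustering: str = "dispersed",
    truth: Optional[synthetic.SimulationTruth] = None,
    noise: str = "poisson",
) -> StudySystem:
    """Simulate the default study system (see module docstring)."""
    pad_years = list(pad_years) if pad_years is not None else list(range(1992, 2012))
    count_years = list(count_years) if count_years is not None else list(range(2002, 2012))
    if truth is None:
        mid_x = 0.5 * (extent[0] + extent[2])
        truth = synthetic.SimulationTruth(
            coefficients={(2.0, 1): synthetic.step_field(mid_x, -4.0, 0.0)},
            baseline=25.0,
            periodicity=(5.0, 6.0),
            noise=noise,
        )
    seed = config.seed
    leks = synthetic.generate_leks(n_leks, extent, seed)
    pads = synthetic.generate_wellpads(
        extent, pad_years, base_intensity, growth=growth,
        clustering=clustering, seed=seed + 1,
    )
    leks = synthetic.generate_counts(leks, pads, truth, count_years, seed=seed + 2)
    return StudySystem(leks=leks, pads=pads, truth=truth, extent=tuple(extent),
                       count_years=tuple(count_years))


def build_design(
    responses: pd.DataFrame,
    densities: pd.DataFrame,
    leks: Sequence[LekSeries],
    kind: str,
    design_keys: Sequence[tuple[float, int]] = DEFAULT_DESIGN_KEYS,
) -> gwr.GWRDesign:
    """Assemble the GWR design for one response kind: intercept plus the
    selected (radius, lag) density columns."""
    keys = [tuple(k) for k in design_keys]
    missing = [k for k in keys if k not in densities.columns]
    if missing:
        raise ContractError(f"density columns missing: {missing}")
    lek_ids = list(responses.index)
    coords = np.array([[lek.x, lek.y] for lek in leks])
    ids = [lek.lek_id for lek in leks]
    if ids != lek_ids:
        order = [ids.index(i) for i in lek_ids]
        coords = coords[order]
    X = np.column_stack(
        [np.ones(len(lek_ids))] + [densities.loc[lek_ids, k].to_numpy() for k in keys]
    )
    names = ["intercept"] + [f"d{r}km_lag{l}" for (r, l) in keys]
    family = "binomial" if kind == "binary" else "gaussian"
    return gwr.GWRDesign(
        y=responses[kind].to_numpy(dtype=float), X=X, coords=coords,
        family=family, covariate_names=names, lek_ids=lek_ids,
    )


def run_pipeline(
    config: AnalysisConfig,
    leks: Sequence[LekSeries],
    pads: Sequence[PadRecord],
    final_year: int,
    design_keys: Sequence[tuple[float, int]] = DEFAULT_DESIGN_KEYS,
    response_kinds: Optional[Sequence[str]] = None,
    trend_window_for_gwr: int = 5,
    out_dir: Optional[Path] = None,
) -> PipelineResult:
    """Run the full analysis on (possibly simulated) lek and pad tables.

    Lags are anchored at the start of the ``trend_window_for_gwr``-year
    response window.  The most supported gaussian trend response (by
    pseudo-R^2) is compared against global OLS with an approximate F test
    and probed with Monte Carlo nonstationarity tests; significant local
    responses are interpolated into IDW surfaces and summarised; response
    lines and sustainable-density thresholds are fitted per design
    covariate.
    """
    eligible = core_io.filter_eligible_leks(list(leks), final_year)
    if len(eligible) < 10:
        raise ContractError(f"only {len(eligible)} eligible leks; need >= 10")

    # responses
    resp_rows = {}
    for lek in eligible:
        resp_rows[lek.lek_id] = {
            k: r.value for k, r in trend.lek_responses(lek, final_year, config).items()
        }
    responses = pd.DataFrame.from_dict(resp_rows, orient="index").sort_index()
    responses.index.name = "lek_id"
    eligible = sorted(eligible, key=lambda l: l.lek_id)

    # lagged density covariates anchored at the GWR response window start
    window_start = final_year - trend_window_for_gwr + 1
    densities = density.density_matrix(eligible, pads, config, window_start)

    if response_kinds is None:
        response_kinds = [f"trend{w}" for w in config.trend_windows]
    fits: dict[str, gwr.GWRFit] = {}
    for kind in response_kinds:
        design = build_design(responses, densities, eligible, kind, design_keys)
        bw = gwr.select_bandwidth(design, kernel=config.kernel, mode=config.bandwidth_mode)
        fits[kind] = gwr.fit_gwr(
            design, config.kernel, bw, adaptive=config.bandwidth_mode == "adaptive"
        )

    # rank gaussian trend responses by pseudo-R^2 (comparison is only valid
    # across the LOWESS trend responses, which share scale and variance)
    trend_kinds = [k for k in fits if k.startswith("trend")]
    best_kind = max(trend_kinds, key=lambda k: fits[k].pseudo_r2)
    best = fits[best_kind]
    _, global_rss = gwr.global_ols(best.design.X, best.design.y)
    anova = gwr.anova_vs_global(best, global_rss, best.n, best.design.p)
    mc = gwr.monte_carlo_nonstationarity(
        best.design, config.kernel, best.bandwidth,
        config.n_permutations, config.seed, adaptive=best.adaptive,
    )

    # mapping of significant local responses for influential covariates
    significant: dict[str, pd.DataFrame] = {}
    surfaces: dict[str, object] = {}
    summaries: dict[str, mapping.RegionSummary] = {}
    coords = best.design.coords
    pad_m = float(np.median(np.ptp(coords, axis=0))) * 0.05
    grid = mapping.GridSpec.covering(coords, config.grid_cell_m, pad=pad_m)
    influential = [
        name
        for name, p in zip(mc.covariate_names, mc.p_values)
        if name != "intercept" and p <= config.alpha
    ]
    for name in influential or [n for n in mc.covariate_names if n != "intercept"][:1]:
        sig = mapping.significant_leks(best, name, config.alpha)
        significant[name] = sig
        if len(sig):
            surfaces[name] = mapping.idw_interpolate(
                sig[["x", "y"]].to_numpy(), sig["local_beta"].to_numpy(),
                grid, power=config.idw_power,
            )
            j = best.design.covariate_names.index(name)
            dens_at_sig = best.design.X[
                [best.design.lek_ids.index(i) for i in sig["lek_id"]], j
            ]
            resp_at_sig = responses.loc[sig["lek_id"], best_kind].to_numpy()
            summaries[name] = mapping.region_summary(dens_at_sig, resp_at_sig)
        else:
            summaries[name] = mapping.region_summary([], [])

    # functional response lines and thresholds per design covariate
    lines: dict[tuple[float, int], object] = {}
    thresholds: dict[tuple[float, int], object] = {}
    current: dict[tuple[float, int], float] = {}
    changes = responses[best_kind].to_numpy(dtype=float)
    for (r, lag) in (tuple(k) for k in design_keys):
        dvals = densities[(r, lag)].to_numpy(dtype=float)
        if np.var(dvals) == 0:
            continue
        line = response.fit_response_line(dvals, changes, r, lag)
        lines[(r, lag)] = line
        if line.slope < 0:
            thresholds[(r, lag)] = response.sustainable_density(line, floor=0.0)
        final_dens = density.roving_density(pads, eligible, r, final_year)
        current[(r, lag)] = float(np.mean([d.value for d in final_dens]))
    forecast = (
        response.forecast_mean_decline(lines, {k: current[k] for k in lines})
        if lines
        else None
    )

    # opposing-response pairs at the first design covariate's density
    r0, l0 = tuple(design_keys[0])
    pairs = mapping.opposing_response_pairs(
        list(responses.index), densities[(r0, l0)].to_numpy(), changes
    )

    # headline summary quantities
    y0, y1 = final_year - 9, final_year
    tot0 = sum(
        lek.records[y0].males for lek in eligible if y0 in lek.records and lek.records[y0].surveyed
    )
    tot1 = sum(
        lek.records[y1].males for lek in eligible if y1 in lek.records and lek.records[y1].surveyed
    )
    summary = {
        "n_eligible_leks": len(eligible),
        "best_response": best_kind,
        "bandwidth": best.bandwidth,
        "gwr_aicc": best.aicc,
        "gwr_pseudo_r2": best.pseudo_r2,
        "anova_F": anova.F,
        "anova_p": anova.p_value,
        "monte_carlo_p": dict(zip(mc.covariate_names, mc.p_values.tolist())),
        "attendance_total_first_year": tot0,
        "attendance_total_final_year": tot1,
        "attendance_percent_change": (
            response.percent_change(tot0, tot1) if tot0 > 0 else math.nan
        ),
        "n_opposing_pairs": len(pairs),
    }

    result = PipelineResult(
        config=config, final_year=final_year, eligible=eligible,
        responses=responses, densities=densities, fits=fits,
        best_kind=best_kind, anova=anova, monte_carlo=mc,
        significant=significant, surfaces=surfaces, region_summaries=summaries,
        lines=lines, thresholds=thresholds, forecast=forecast,
        opposing_pairs=pairs, summary=summary,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    responses_long = result.responses.reset_index().melt(
        id_vars="lek_id", var_name="kind", value_name="value"
    )
    responses_long.to_csv(out_dir / "responses.csv", index=False)
    window_start = result.final_year - 9
    density.density_table_long(result.densities, window_start).to_csv(
        out_dir / "densities.csv", index=False
    )
    best = result.fits[result.best_kind]
    per_lek = pd.DataFrame(
        {
            "lek_id": best.design.lek_ids,
            "x": best.design.coords[:, 0],
            "y": best.design.coords[:, 1],
        }
    )
    for j, name in enumerate(best.design.covariate_names):
        per_lek[f"beta_{name}"] = best.local_beta[:, j]
        per_lek[f"se_{name}"] = best.local_se[:, j]
        per_lek[f"t_{name}"] = best.local_t[:, j]
    per_lek.to_csv(out_dir / "gwr_local.csv", index=False)
    core_io.write_geojson_points(per_lek.to_dict("records"), out_dir / "gwr_local.geojson")
    for name, surf in result.surfaces.items():
        mapping.write_asc(surf, out_dir / f"surface_{name}.asc")
    model = dict(result.summary)
    model["lines"] = {
        f"{r}km_lag{l}": {"slope": ln.slope, "intercept": ln.intercept}
        for (r, l), ln in result.lines.items()
    }
    model["thresholds"] = {
        f"{r}km_lag{l}": {"density": th.density, "pad_count": th.pad_count}
        for (r, l), th in result.thresholds.items()
    }
    if result.forecast is not None:
        model["forecast"] = {
            "aggregate": result.forecast.aggregate,
            "per_line": {f"{r}km_lag{l}": v for (r, l), v in result.forecast.per_line.items()},
        }
    (out_dir / "model_summary.json").write_text(json.dumps(model, indent=1, default=float))
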