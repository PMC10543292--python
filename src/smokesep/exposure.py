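"""Population exposure and attainment metrics from the separated fields.

Turns per-cell-day smoke and total PM2.5 fields into the policy-facing
quantities: smoke-impact days (smoke above a share of total), the fraction
of the monitor network affected for at least a month, population exposure
stratified by proximity to a regulatory monitor, and design-value
nonattainment under candidate annual standards (a design value is the
trailing multi-year mean of annual means; a location is nonattaining when
its design value is at or above the standard).

A published national 2007–2018 exposure summary (one row per year, columns
matching :func:`population_exposure_summary` output) ships with the package
as ``data/conus_exposure_2007_2018.csv`` for worked examples and regression
tests of :func:`summarize_years`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

EXPOSURE_COLUMNS = [
    "year",
    "total_pop",
    "pop_no_aqs",
    "smoke_impacted_pop",
    "smoke_impacted_pop_no_aqs",
    "impact_days_aqs",
    "impact_days_no_aqs",
    "mean_total_pm_aqs",
    "mean_smoke_pm_aqs",
    "mean_total_pm_no_aqs",
    "mean_smoke_pm_no_aqs",
]

__all__ = [
    "EXPOSURE_COLUMNS",
    "AttainmentResult",
    "load_reference_exposure_table",
    "smoke_impact_days",
    "monitor_impact_fraction",
    "vicinity_mask",
    "population_exposure_summary",
    "summarize_years",
    "design_values",
    "nonattainment",
]


def load_reference_exposure_table() -> pd.DataFrame:
    """The published CONUS 2007–2018 yearly exposure summary (12 rows)."""
    with resources.files("smokesep.data").joinpath("conus_exposure_2007_2018.csv").open() as f:
        return pd.read_csv(f)


def smoke_impact_days(
    smoke: np.ndarray,
    total: np.ndarray,
    days_per_year: int,
    share_threshold: float = 0.25,
) -> np.ndarray:
    """Count smoke-impact days per cell-year.

    A day counts when smoke strictly exceeds ``share_threshold`` of total
    PM2.5; days with zero total never count. Fields are (n_days, ny, nx);
    the result is (n_years, ny, nx) of integer counts.
    """
    smoke = np.asarray(smoke, float)
    total = np.asarray(total, float)
    if smoke.shape != total.shape:
        raise ValueError("smoke and total fields must share a shape")
    n_days = smoke.shape[0]
    if n_days % days_per_year != 0:
        raise ValueError("n_days must be a multiple of days_per_year")
    with np.errstate(invalid="ignore", divide="ignore"):
        hit = (total > 0) & (smoke / np.where(total > 0, total, 1.0) > share_threshold)
    n_years = n_days // days_per_year
    return hit.reshape(n_years, days_per_year, *smoke.shape[1:]).sum(axis=1)


def monitor_impact_fraction(
    counts: np.ndarray,
    monitor_iy: np.ndarray,
    monitor_ix: np.ndarray,
    min_days: int = 30,
) -> np.ndarray:
    """Per-year fraction of monitors with at least ``min_days`` impact days.

    ``counts`` is the (n_years, ny, nx) output of :func:`smoke_impact_days`;
    monitors are given by their cell indices. "Affected for more than a
    month" is operationalized as ``counts >= min_days`` (default 30 days).
    """
    monitor_iy = np.asarray(monitor_iy)
    if monitor_iy.size == 0:
        raise ValueError("no monitors")
    at_monitors = counts[:, monitor_iy, np.asarray(monitor_ix)]  # (n_years, n_monitors)
    return (at_monitors >= min_days).mean(axis=1)


def vicinity_mask(
    monitor_x: np.ndarray, monitor_y: np.ndarray, grid, radius_km: float = 5.0
) -> np.ndarray:
    """(ny, nx) bool: cell centers within ``radius_km`` of any monitor."""
    xx, yy = grid.center_mesh()
    mask = np.zeros((grid.ny, grid.nx), dtype=bool)
    for x, y in zip(np.atleast_1d(monitor_x), np.atleast_1d(monitor_y)):
        mask |= np.hypot(xx - x, yy - y) <= radius_km
    return mask


def _pop_weighted_mean(values: np.ndarray, pop: np.ndarray, mask: np.ndarray) -> float:
    w = pop[mask]
    if w.sum() <= 0:
        return np.nan
    return float(np.average(values[mask], weights=w))


def population_exposure_summary(
    smoke: np.ndarray,
    total: np.ndarray,
    counts: np.ndarray,
    population: np.ndarray,
    mask: np.ndarray,
    days_per_year: int,
    pop_scale: float = 1e6,
) -> pd.DataFrame:
    """Yearly exposure summary stratified by monitor vicinity.

    Per year: population totals inside/outside the vicinity mask (reported
    in units of ``pop_scale`` persons); "smoke impacted" population lives in
    cells with at least one impact day; ``impact_days_*`` are
    population-weighted means of cell impact-day counts per stratum; the
    PM2.5 columns are population-weighted annual means of the total and
    smoke fields per stratum. One row per year, columns
    :data:`EXPOSURE_COLUMNS`.
    """
    n_years = counts.shape[0]
    if population.shape[0] != n_years:
        raise ValueError("population must have one layer per year")
    rows = []
    for y in range(n_years):
        sl = slice(y * days_per_year, (y + 1) * days_per_year)
        total_mean = total[sl].mean(axis=0)
        smoke_mean = smoke[sl].mean(axis=0)
        pop = population[y]
        impacted = counts[y] >= 1
        out = ~mask
        rows.append(
            {
                "year": y,
                "total_pop": pop.sum() / pop_scale,
                "pop_no_aqs": pop[out].sum() / pop_scale,
                "smoke_impacted_pop": pop[impacted].sum() / pop_scale,
                "smoke_impacted_pop_no_aqs": pop[impacted & out].sum() / pop_scale,
                "impact_days_aqs": _pop_weighted_mean(counts[y], pop, mask),
                "impact_days_no_aqs": _pop_weighted_mean(counts[y], pop, out),
                "mean_total_pm_aqs": _pop_weighted_mean(total_mean, pop, mask),
                "mean_smoke_pm_aqs": _pop_weighted_mean(smoke_mean, pop, mask),
                "mean_total_pm_no_aqs": _pop_weighted_mean(total_mean, pop, out),
                "mean_smoke_pm_no_aqs": _pop_weighted_mean(smoke_mean, pop, out),
            }
        )
    return pd.DataFrame(rows, columns=EXPOSURE_COLUMNS)


def summarize_years(rows: pd.DataFrame) -> dict:
    """Multi-year summary of a yearly exposure table.

    Column means are unweighted means over years. The headline vicinity
    contrast is the mean over years of the yearly percent excess
    ``100 * (impact_days_no_aqs - impact_days_aqs) / impact_days_aqs``
    (mean of yearly percentages, deliberately not the percentage of the
    means), with the years attaining its minimum and maximum. Years with
    zero in-vicinity impact days are excluded from the excess with a
    warning. Also reports the per-year smoke-impacted population percentage.
    """
    if rows.empty:
        raise ValueError("need at least one yearly row")
    means = {f"mean_{c}": float(rows[c].mean()) for c in rows.columns if c != "year"}

    valid = rows["impact_days_aqs"] != 0
    if not valid.all():
        warnings.warn(
            f"{int((~valid).sum())} year(s) with zero in-vicinity impact days "
            "excluded from the percent-excess summary"
        )
    sub = rows[valid]
    pct = 100.0 * (sub["impact_days_no_aqs"] - sub["impact_days_aqs"]) / sub["impact_days_aqs"]
    excess = {
        "pct_excess_by_year": dict(zip(sub["year"].tolist(), pct.round(6).tolist())),
        "mean_pct_excess": float(pct.mean()) if len(pct) else np.nan,
        "min_pct_excess": float(pct.min()) if len(pct) else np.nan,
        "min_pct_excess_year": int(sub["year"].iloc[int(np.argmin(pct.to_numpy()))]) if len(pct) else None,
        "max_pct_excess": float(pct.max()) if len(pct) else np.nan,
        "max_pct_excess_year": int(sub["year"].iloc[int(np.argmax(pct.to_numpy()))]) if len(pct) else None,
    }
    impacted_pct = (100.0 * rows["smoke_impacted_pop"] / rows["total_pop"]).round(6)
    return {
        **means,
        **excess,
        "impacted_pop_pct_by_year": dict(zip(rows["year"].tolist(), impacted_pct.tolist())),
    }


def design_values(annual_means: np.ndarray, window: int = 3) -> np.ndarray:
    """Trailing-window mean of annual means per location.

    ``annual_means`` is (n_years, ...); the result has one layer per
    terminal year with at least ``window - 1`` predecessors, i.e. shape
    (n_years - window + 1, ...).
    """
    annual_means = np.asarray(annual_means, float)
    n_years = annual_means.shape[0]
    if n_years < window:
        raise ValueError(f"need at least {window} years of annual means")
    return np.stack(
        [annual_means[y - window + 1 : y + 1].mean(axis=0) for y in range(window - 1, n_years)]
    )


@dataclass
class AttainmentResult:
    """Nonattainment under one threshold/scenario for one design-value year."""

    threshold: float
    scenario: str  # "with_smoke" | "without_smoke"
    year: int
    n_monitors: int
    nonattaining_monitors: int
    monitor_fraction: float
    nonattaining_population: float  # in pop_scale units
    nonattaining_cells: int


def nonattainment(
    dv: np.ndarray,
    threshold: float,
    scenario: str,
    population: np.ndarray,
    monitor_iy: np.ndarray,
    monitor_ix: np.ndarray,
    year: int = 0,
    pop_scale: float = 1e6,
) -> AttainmentResult:
    """Nonattainment status for one design-value layer.

    A cell (or monitor cell) is nonattaining iff its design value is greater
    than or equal to ``threshold`` (inclusive). ``population`` is the (ny,
    nx) layer of the design value's terminal year; the affected population
    is summed over nonattaining cells.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    dv = np.asarray(dv, float)
    if np.isnan(dv).any():
        raise ValueError("design values contain missing entries")
    bad = dv >= threshold
    monitor_iy = np.asarray(monitor_iy)
    monitor_ix = np.asarray(monitor_ix)
    at_monitors = bad[monitor_iy, monitor_ix]
    n_mon = int(monitor_iy.size)
    return AttainmentResult(
        threshold=threshold,
        scenario=scenario,
        year=year,
        n_monitors=n_mon,
        nonattaining_monitors=int(at_monitors.sum()),
        monitor_fraction=float(at_monitors.mean()) if n_mon else np.nan,
        nonattaining_population=float(population[bad].sum() / pop_scale),
        nonattaining_cells=int(bad.sum()),
    )
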