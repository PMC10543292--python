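"""Assemble the per-cell-day feature table for the separation models.

Brings every product onto the common 1-km grid: coarse fields are
interpolated with inverse-distance weighting, the cloud-masked satellite AOD
is gap-filled, plume polygons are rasterised into duration/density features,
ground observations are averaged into their cells, and each cell-day is
labelled smoke or no-smoke (inside a plume polygon, or CTM smoke ratio above
a threshold).

The feature table is a DataFrame with one row per cell-day. The no-smoke
(background) model uses the no-fire CTM run plus the shared covariates
(:data:`BACKGROUND_FEATURES`); the smoke-region (total) model uses the
with-fire CTM run plus, additionally, the plume features
(:data:`SMOKE_FEATURES`).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import uniform_filter
from scipy.spatial import cKDTree

from .calibration import RegionPartition
from .world import CTMFields, GridSpec, PlumePolygon, World

# covariates shared by both models (the Z vector)
SHARED_FEATURES = [
    "aod",
    "temp_f",
    "rh",
    "wind_u",
    "wind_v",
    "cloud",
    "elevation",
    "frac_urban",
    "frac_forest",
    "road_km",
    "pop_density",
    "climate_region",
]
BACKGROUND_FEATURES = ["ctm_background"] + SHARED_FEATURES
SMOKE_FEATURES = ["ctm_total"] + SHARED_FEATURES + ["plume_duration", "plume_density"]

__all__ = [
    "SHARED_FEATURES",
    "BACKGROUND_FEATURES",
    "SMOKE_FEATURES",
    "idw_regrid",
    "gap_fill_aod",
    "plume_features",
    "assign_observations",
    "label_smoke",
    "build_feature_table",
]


def idw_regrid(
    node_xy: np.ndarray,
    node_values: np.ndarray,
    grid: GridSpec,
    power: float = 2.0,
    k: int = 4,
) -> np.ndarray:
    """Inverse-distance-weighted interpolation of node values onto the grid.

    Each cell center takes ``Σ w_j v_j / Σ w_j`` over its ``k`` nearest
    nodes with ``w_j = d_j^-power``; a cell exactly collocated with a node
    returns that node's value. ``node_values`` may be ``(n_nodes,)`` or
    ``(n_days, n_nodes)``; the output is ``(ny, nx)`` or ``(n_days, ny, nx)``.
    """
    node_xy = np.asarray(node_xy, dtype=float)
    node_values = np.asarray(node_values, dtype=float)
    if node_xy.ndim != 2 or node_xy.shape[0] < 1:
        raise ValueError("need at least one coarse node")
    k = min(k, node_xy.shape[0])
    tree = cKDTree(node_xy)
    dist, idx = tree.query(grid.cell_centers(), k=k)
    dist = np.atleast_2d(dist.reshape(-1, k))
    idx = np.atleast_2d(idx.reshape(-1, k))

    exact = dist[:, 0] < 1e-12
    with np.errstate(divide="ignore"):
        w = dist ** (-power)
    w[exact] = 0.0
    w[exact, 0] = 1.0  # collocated query: copy the node value

    squeeze = node_values.ndim == 1
    vals = node_values[None, :] if squeeze else node_values  # (n_days, n_nodes)
    num = np.einsum("qk,dqk->dq", w, vals[:, idx])
    out = (num / w.sum(axis=1)[None, :]).reshape(-1, grid.ny, grid.nx)
    return out[0] if squeeze else out


def gap_fill_aod(
    aod: np.ndarray,
    coarse_aod: np.ndarray | None,
    covariates: Mapping[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Fill missing satellite AOD cells to full coverage.

    Two steps: (1) regress observed AOD on the regridded coarse AOD and any
    covariates (pooled linear model over all observed cell-days) and fill
    gaps with fitted values; (2) smooth the filled cells only with a 3x3
    spatial mean of surrounding (observed or filled) values. Observed cells
    pass through unchanged.

    ``aod`` is (n_days, ny, nx) with NaN gaps; ``coarse_aod`` is a full
    field of the same shape (or None if covariates alone must carry the
    regression); covariates are (n_days, ny, nx) or static (ny, nx) fields.
    """
    aod = np.asarray(aod, dtype=float)
    missing = np.isnan(aod)
    if not missing.any():
        return aod.copy()

    preds: list[np.ndarray] = []
    if coarse_aod is not None:
        preds.append(np.broadcast_to(coarse_aod, aod.shape))
    for name in sorted(covariates) if covariates else []:
        preds.append(np.broadcast_to(covariates[name], aod.shape))
    if not preds:
        raise ValueError("gap filling needs a coarse AOD field or covariates")

    X = np.column_stack([np.ones(aod.size)] + [p.reshape(-1) for p in preds])
    obs = ~missing.reshape(-1)
    if not obs.any():
        raise ValueError("no observed AOD anywhere: cannot fit the gap-fill regression")
    beta, *_ = np.linalg.lstsq(X[obs], aod.reshape(-1)[obs], rcond=None)
    fitted = (X @ beta).reshape(aod.shape)

    filled = np.where(missing, fitted, aod)
    # step 2: 3x3 neighbourhood mean, applied to the filled cells only
    smoothed = np.stack(
        [uniform_filter(filled[d], size=3, mode="nearest") for d in range(filled.shape[0])]
    )
    out = np.where(missing, smoothed, aod)
    return out


def _covering_mask(poly, grid: GridSpec) -> np.ndarray:
    """(ny, nx) bool: cell centers covered by the polygon (boundary counts)."""
    xx, yy = grid.center_mesh()
    return shapely.intersects_xy(poly, xx.ravel(), yy.ravel()).reshape(grid.ny, grid.nx)


def plume_features(
    polygons: Sequence[PlumePolygon], grid: GridSpec, date: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell plume duration (hours, capped at 24) and weighted density.

    For each cell whose center lies inside at least one of the date's
    polygons, duration is the sum of the polygons' observation windows and
    weighted density is the duration-weighted mean of their density classes.
    Uncovered cells get (0, 0). Degenerate polygons are skipped with a
    warning.
    """
    dur = np.zeros((grid.ny, grid.nx))
    dens_sum = np.zeros((grid.ny, grid.nx))
    for p in polygons:
        if p.date != date:
            continue
        if p.polygon.is_empty or p.polygon.area == 0:
            warnings.warn(f"degenerate plume polygon on day {p.date} skipped")
            continue
        mask = _covering_mask(p.polygon, grid)
        hours = p.duration_hours
        dur[mask] += hours
        dens_sum[mask] += p.density_class * hours
    with np.errstate(invalid="ignore"):
        dens = np.where(dur > 0, dens_sum / dur, 0.0)
    return np.minimum(dur, 24.0), dens


def assign_observations(observations: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    """Average ground observations into their grid cells per day.

    ``observations`` needs ``site_id, x_km, y_km, date, pm25``; all sources
    (reference and selected calibrated low-cost) are averaged together in
    cells holding several monitors. Raises for sites outside the grid,
    naming them. Returns columns ``date, iy, ix, obs_pm25``.
    """
    if observations.empty:
        return pd.DataFrame(columns=["date", "iy", "ix", "obs_pm25"])
    try:
        iy, ix = grid.cell_of(observations["x_km"].to_numpy(), observations["y_km"].to_numpy())
    except ValueError:
        inside_x = observations["x_km"].between(
            grid.origin[0], grid.origin[0] + grid.nx * grid.cell_km
        )
        inside_y = observations["y_km"].between(
            grid.origin[1], grid.origin[1] + grid.ny * grid.cell_km
        )
        bad = observations.loc[~(inside_x & inside_y), "site_id"].unique().tolist()
        raise ValueError(f"site(s) outside grid: {bad}") from None
    df = pd.DataFrame(
        {"date": observations["date"].to_numpy(), "iy": iy, "ix": ix, "obs_pm25": observations["pm25"].to_numpy()}
    )
    return df.groupby(["date", "iy", "ix"], as_index=False)["obs_pm25"].mean()


def label_smoke(
    polygons: Sequence[PlumePolygon],
    ctm: CTMFields,
    grid: GridSpec,
    ratio_threshold: float = 0.03,
) -> np.ndarray:
    """Boolean (n_days, ny, nx) smoke labels.

    A cell-day is smoke-impacted iff its center lies inside any same-day
    plume polygon OR the CTM smoke ratio strictly exceeds
    ``ratio_threshold``.
    """
    label = ctm.smoke_ratio > ratio_threshold
    for p in polygons:
        if 0 <= p.date < label.shape[0]:
            label[p.date] |= _covering_mask(p.polygon, grid)
    return label


def build_feature_table(
    world: World,
    observations: pd.DataFrame,
    ratio_threshold: float = 0.03,
    idw_power: float = 2.0,
    idw_k: int = 4,
    regions: RegionPartition | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the smoke and no-smoke cell-day feature tables.

    Returns ``(smoke_table, background_table)``: a partition of all cell-days
    by the smoke label. Both carry the shared covariates; the smoke table
    additionally carries the with-fire CTM field and plume features, the
    background table the no-fire CTM field. ``obs_pm25`` is NaN where no
    monitor reports; rows with an observation are the training subsets.
    """
    grid = world.grid
    truth = world.truth
    regions = regions or RegionPartition.quadrants(grid)
    n_days, ny, nx = truth.background.shape

    # satellite AOD with cloud-driven gaps, then regrid + gap-fill
    aod_obs = np.where(truth.cloud > world.config.cloud_missing_threshold, np.nan, truth.aod_true)
    coarse_fine = idw_regrid(world.coarse_aod_xy, world.coarse_aod, grid, power=idw_power, k=idw_k)
    wind_speed = np.hypot(truth.wind_u, truth.wind_v)
    aod = gap_fill_aod(
        aod_obs, coarse_fine, {"temp_f": truth.temp_f, "rh": truth.rh, "wind": wind_speed}
    )

    plume_dur = np.zeros((n_days, ny, nx))
    plume_dens = np.zeros((n_days, ny, nx))
    dates_with_plumes = {p.date for p in world.plumes}
    for d in dates_with_plumes:
        plume_dur[d], plume_dens[d] = plume_features(world.plumes, grid, d)

    label = label_smoke(world.plumes, world.ctm, grid, ratio_threshold=ratio_threshold)

    xx, yy = grid.center_mesh()
    climate = regions.region_of(xx, yy).astype(float)
    day = np.repeat(np.arange(n_days), ny * nx)
    year_of_day = np.arange(n_days) // grid.days_per_year
    pop_density = truth.population[year_of_day]  # (n_days, ny, nx)

    def flat(a: np.ndarray) -> np.ndarray:
        return np.broadcast_to(a, (n_days, ny, nx)).reshape(-1)

    iy_grid, ix_grid = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    table = pd.DataFrame(
        {
            "date": day,
            "iy": flat(iy_grid[None]),
            "ix": flat(ix_grid[None]),
            "aod": aod.reshape(-1),
            "temp_f": truth.temp_f.reshape(-1),
            "rh": truth.rh.reshape(-1),
            "wind_u": truth.wind_u.reshape(-1),
            "wind_v": truth.wind_v.reshape(-1),
            "cloud": truth.cloud.reshape(-1),
            "elevation": flat(truth.elevation[None]),
            "frac_urban": flat(truth.frac_urban[None]),
            "frac_forest": flat(truth.frac_forest[None]),
            "road_km": flat(truth.road_km[None]),
            "pop_density": pop_density.reshape(-1),
            "climate_region": flat(climate[None]),
            "ctm_background": world.ctm.background.reshape(-1),
            "ctm_total": world.ctm.total.reshape(-1),
            "plume_duration": plume_dur.reshape(-1),
            "plume_density": plume_dens.reshape(-1),
            "smoke": label.reshape(-1),
        }
    )
    table["cell_id"] = grid.cell_id(table["iy"], table["ix"])

    obs = assign_observations(observations, grid)
    if not obs.empty:
        table = table.merge(obs, on=["date", "iy", "ix"], how="left")
    else:
        table["obs_pm25"] = np.nan

    # the boolean label column is kept so downstream code can assert the
    # contract (e.g. predict_smoke refuses no-smoke rows)
    smoke_table = table[table["smoke"]].reset_index(drop=True)
    background_table = table[~table["smoke"]].reset_index(drop=True)
    return smoke_table, background_table
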