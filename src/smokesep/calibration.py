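"""Low-cost sensor quality control and regional GWR calibration.

Dual-channel low-cost optical sensors over-read PM2.5 with a humidity- and
temperature-dependent bias. The workflow here mirrors regulatory practice:

1. hourly records are screened (completeness, channel agreement, physical
   bounds) and aggregated to daily values;
2. sensor-days are paired with the nearest reference monitor within a small
   radius;
3. a geographically weighted regression (GWR) of reference PM2.5 on raw
   sensor PM2.5, relative humidity and temperature is fitted per region, so
   the correction varies smoothly in space;
4. predictions are blended across region boundaries inside a buffer, and
   only calibrated values above a concentration threshold are passed on to
   model training.

Daily observation tables are plain DataFrames with columns
``site_id, x_km, y_km, date, pm25, rh, temp_f, source``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

OBS_COLUMNS = ["site_id", "x_km", "y_km", "date", "pm25", "rh", "temp_f", "source"]

__all__ = [
    "OBS_COLUMNS",
    "QCRules",
    "RegionPartition",
    "CalibrationModel",
    "qc_daily_aggregate",
    "aggregate_reference",
    "pair_sensors",
    "fit_regional_gwr",
    "calibrate",
    "select_for_training",
]


@dataclass(frozen=True)
class QCRules:
    """Screening rules for hourly sensor data.

    A sensor-day survives only if each channel has at least ``min_hours``
    hourly values, the symmetric relative difference of the two channel
    daily means is at most ``max_channel_rel_diff``, the daily mean is at
    most ``max_daily_pm25`` µg/m³, and daily mean temperature / RH lie in
    the stated physical bounds.
    """

    min_hours: int = 16
    max_channel_rel_diff: float = 0.30
    max_daily_pm25: float = 1000.0
    temp_min_f: float = -20.0
    temp_max_f: float = 140.0
    rh_min: float = 0.0
    rh_max: float = 100.0


def _attach_sites(daily: pd.DataFrame, sites: pd.DataFrame | None) -> pd.DataFrame:
    if sites is None:
        return daily
    locs = sites.set_index("site_id")[["x_km", "y_km"]]
    daily = daily.merge(locs, left_on="site_id", right_index=True, how="left")
    return daily


def qc_daily_aggregate(
    hourly: pd.DataFrame,
    rules: QCRules = QCRules(),
    sites: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Screen dual-channel hourly records and aggregate to daily values.

    ``hourly`` needs columns ``site_id, date, hour, pm_a, pm_b, temp_f, rh``.
    The surviving daily PM2.5 is the mean of the two channel daily means;
    daily RH and temperature are hourly means. Empty input yields an empty
    table, not an error. Returns observations with ``source='lowcost_raw'``.
    """
    if hourly.empty:
        return pd.DataFrame(columns=OBS_COLUMNS)

    g = hourly.groupby(["site_id", "date"], sort=True)
    agg = g.agg(
        n_a=("pm_a", "count"),
        n_b=("pm_b", "count"),
        mean_a=("pm_a", "mean"),
        mean_b=("pm_b", "mean"),
        rh=("rh", "mean"),
        temp_f=("temp_f", "mean"),
    ).reset_index()

    mean_ab = 0.5 * (agg["mean_a"] + agg["mean_b"])
    with np.errstate(invalid="ignore", divide="ignore"):
        rel_diff = np.abs(agg["mean_a"] - agg["mean_b"]) / mean_ab
    rel_diff = rel_diff.fillna(0.0)  # both channels at exactly 0 agree perfectly

    keep = (
        (agg["n_a"] >= rules.min_hours)
        & (agg["n_b"] >= rules.min_hours)
        & (rel_diff <= rules.max_channel_rel_diff)
        & (mean_ab <= rules.max_daily_pm25)
        & agg["temp_f"].between(rules.temp_min_f, rules.temp_max_f)
        & agg["rh"].between(rules.rh_min, rules.rh_max)
    )
    out = agg.loc[keep, ["site_id", "date", "rh", "temp_f"]].copy()
    out["pm25"] = mean_ab[keep]
    out["source"] = "lowcost_raw"
    out = _attach_sites(out, sites)
    for col in ("x_km", "y_km"):
        if col not in out.columns:
            out[col] = np.nan
    return out[OBS_COLUMNS].reset_index(drop=True)


def aggregate_reference(
    hourly: pd.DataFrame,
    min_hours: int = 16,
    sites: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Aggregate single-channel reference records to daily means.

    Station-days with fewer than ``min_hours`` of the 24 possible hourly
    values are dropped; no channel or extreme-value screening applies to
    reference-grade data. Returns observations with ``source='reference'``.
    """
    if hourly.empty:
        return pd.DataFrame(columns=OBS_COLUMNS)
    g = hourly.groupby(["site_id", "date"], sort=True)["pm25"].agg(["count", "mean"]).reset_index()
    out = g.loc[g["count"] >= min_hours, ["site_id", "date"]].copy()
    out["pm25"] = g.loc[g["count"] >= min_hours, "mean"].to_numpy()
    out["source"] = "reference"
    out["rh"] = np.nan
    out["temp_f"] = np.nan
    out = _attach_sites(out, sites)
    for col in ("x_km", "y_km"):
        if col not in out.columns:
            out[col] = np.nan
    return out[OBS_COLUMNS].reset_index(drop=True)


def pair_sensors(
    lowcost: pd.DataFrame, reference: pd.DataFrame, radius_km: float = 5.0
) -> pd.DataFrame:
    """Pair each sensor-day with its nearest reference monitor within radius.

    Each low-cost sensor is matched to the single nearest reference site
    within ``radius_km`` (ties broken toward the lexicographically smaller
    reference ``site_id``); the pair table keeps only dates on which both
    report. Columns: ``site_id, ref_site_id, date, x_km, y_km, raw_pm25,
    ref_pm25, rh, temp_f, distance_km``.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    cols = [
        "site_id",
        "ref_site_id",
        "date",
        "x_km",
        "y_km",
        "raw_pm25",
        "ref_pm25",
        "rh",
        "temp_f",
        "distance_km",
    ]
    if lowcost.empty or reference.empty:
        return pd.DataFrame(columns=cols)

    ref_sites = (
        reference[["site_id", "x_km", "y_km"]].drop_duplicates("site_id").sort_values("site_id")
    )
    lc_sites = lowcost[["site_id", "x_km", "y_km"]].drop_duplicates("site_id")

    ref_xy = ref_sites[["x_km", "y_km"]].to_numpy()
    matches = {}
    for sid, x, y in lc_sites.itertuples(index=False):
        d = np.hypot(ref_xy[:, 0] - x, ref_xy[:, 1] - y)
        j = int(np.argmin(d))  # ref_sites sorted by id → first minimum is the tie-break
        if d[j] <= radius_km:
            matches[sid] = (ref_sites["site_id"].iat[j], float(d[j]))
    if not matches:
        return pd.DataFrame(columns=cols)

    lc = lowcost[lowcost["site_id"].isin(matches)].copy()
    lc["ref_site_id"] = lc["site_id"].map(lambda s: matches[s][0])
    lc["distance_km"] = lc["site_id"].map(lambda s: matches[s][1])
    ref_vals = reference[["site_id", "date", "pm25"]].rename(
        columns={"site_id": "ref_site_id", "pm25": "ref_pm25"}
    )
    pairs = lc.merge(ref_vals, on=["ref_site_id", "date"], how="inner")
    pairs = pairs.rename(columns={"pm25": "raw_pm25"})
    return pairs[cols].reset_index(drop=True)


@dataclass(frozen=True)
class RegionPartition:
    """Axis-aligned partition of the domain into four rectangular regions.

    Regions are numbered 1..4 as (SW, SE, NW, NE) around the split point
    ``(x_split, y_split)``. Used both for regional calibration models and as
    the synthetic world's climate-region indicator.
    """

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    x_split: float
    y_split: float

    @classmethod
    def quadrants(cls, grid) -> "RegionPartition":
        x0, y0 = grid.origin
        return cls(
            x_min=x0,
            x_max=x0 + grid.nx * grid.cell_km,
            y_min=y0,
            y_max=y0 + grid.ny * grid.cell_km,
            x_split=x0 + grid.nx * grid.cell_km / 2.0,
            y_split=y0 + grid.ny * grid.cell_km / 2.0,
        )

    @property
    def region_ids(self) -> tuple[int, ...]:
        return (1, 2, 3, 4)

    def region_of(self, x, y) -> np.ndarray:
        """Region id (1..4) for each point; boundary points go east/north."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (1 + (x >= self.x_split) + 2 * (y >= self.y_split)).astype(int)

    def boundary_distance(self, x, y) -> dict[int, np.ndarray]:
        """Distance from each point to every region's rectangle (0 inside)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out: dict[int, np.ndarray] = {}
        for rid in self.region_ids:
            xlo = self.x_min if rid in (1, 3) else self.x_split
            xhi = self.x_split if rid in (1, 3) else self.x_max
            ylo = self.y_min if rid in (1, 2) else self.y_split
            yhi = self.y_split if rid in (1, 2) else self.y_max
            dx = np.maximum(np.maximum(xlo - x, x - xhi), 0.0)
            dy = np.maximum(np.maximum(ylo - y, y - yhi), 0.0)
            out[rid] = np.hypot(dx, dy)
        return out


@dataclass
class CalibrationModel:
    """One region's geographically weighted calibration regression.

    Coefficients at a query location solve weighted least squares of
    ``reference ~ 1 + raw + rh + temp`` over the region's pairs with Gaussian
    kernel weights ``w_i = exp(-(d_i / bandwidth)^2)``.
    """

    region_id: int
    bandwidth_km: float
    kernel: str = "gaussian"
    xy: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    design: np.ndarray = field(default_factory=lambda: np.empty((0, 4)))
    target: np.ndarray = field(default_factory=lambda: np.empty(0))

    N_COEF = 4  # intercept, raw, rh, temp

    def __post_init__(self) -> None:
        if self.bandwidth_km <= 0:
            raise ValueError("bandwidth must be positive")
        if self.kernel != "gaussian":
            raise ValueError(f"unsupported kernel {self.kernel!r}")

    @classmethod
    def fit(
        cls, region_id: int, pairs: pd.DataFrame, bandwidth_km: float, kernel: str = "gaussian"
    ) -> "CalibrationModel":
        if len(pairs) < cls.N_COEF + 1:
            raise ValueError(
                f"region {region_id}: {len(pairs)} pairs, need >= {cls.N_COEF + 1}"
            )
        design = np.column_stack(
            [
                np.ones(len(pairs)),
                pairs["raw_pm25"].to_numpy(float),
                pairs["rh"].to_numpy(float),
                pairs["temp_f"].to_numpy(float),
            ]
        )
        model = cls(
            region_id=region_id,
            bandwidth_km=bandwidth_km,
            kernel=kernel,
            xy=pairs[["x_km", "y_km"]].to_numpy(float),
            design=design,
            target=pairs["ref_pm25"].to_numpy(float),
        )
        # fail fast on a globally singular design (e.g. constant covariate)
        model.coefficients_at(model.xy[:, 0].mean(), model.xy[:, 1].mean())
        return model

    def _weights(self, x: float, y: float) -> np.ndarray:
        d = np.hypot(self.xy[:, 0] - x, self.xy[:, 1] - y)
        return np.exp(-((d / self.bandwidth_km) ** 2))

    def coefficients_at(self, x: float, y: float) -> np.ndarray:
        """(β0, β_pm, β_rh, β_t) from the local weighted least squares."""
        w = np.sqrt(self._weights(x, y))
        if np.count_nonzero(w) < self.N_COEF:
            raise ValueError(f"region {self.region_id}: too few effective pairs at ({x}, {y})")
        A = self.design * w[:, None]
        b = self.target * w
        beta, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
        if rank < self.N_COEF:
            raise ValueError(
                f"region {self.region_id}: singular weighted design at ({x}, {y})"
            )
        return beta

    def predict(self, x: float, y: float, raw: np.ndarray, rh: np.ndarray, temp_f: np.ndarray) -> np.ndarray:
        beta = self.coefficients_at(x, y)
        pred = beta[0] + beta[1] * np.asarray(raw) + beta[2] * np.asarray(rh) + beta[3] * np.asarray(temp_f)
        return np.maximum(pred, 0.0)


def fit_regional_gwr(
    pairs: pd.DataFrame,
    regions: RegionPartition,
    bandwidth_km: float = 15.0,
    kernel: str = "gaussian",
) -> dict[int, CalibrationModel]:
    """Fit one GWR calibration model per region containing pairs.

    Regions with too few pairs for the 4-coefficient fit are skipped with a
    warning (callers get an explicit error later only if a sensor actually
    needs the missing region).
    """
    models: dict[int, CalibrationModel] = {}
    if pairs.empty:
        return models
    rid = regions.region_of(pairs["x_km"].to_numpy(), pairs["y_km"].to_numpy())
    for r in regions.region_ids:
        sub = pairs[rid == r]
        if len(sub) < CalibrationModel.N_COEF + 1:
            warnings.warn(f"region {r}: only {len(sub)} pairs, no calibration model fitted")
            continue
        models[r] = CalibrationModel.fit(r, sub, bandwidth_km, kernel)
    return models


def calibrate(
    lowcost: pd.DataFrame,
    models: dict[int, CalibrationModel],
    regions: RegionPartition,
    blend_buffer_km: float = 20.0,
) -> pd.DataFrame:
    """Apply regional calibration with boundary blending.

    A sensor farther than ``blend_buffer_km`` from every other region uses
    its own region's model. A sensor within the buffer of one or more
    neighbouring regions receives the unweighted mean of all adjacent
    regions' predictions (two at an edge, up to four at the corner).
    Returns a table with ``source='lowcost_calibrated'`` and pm25 floored
    at 0.
    """
    if lowcost.empty:
        out = lowcost.copy()
        out["source"] = "lowcost_calibrated"
        return out

    out = lowcost.copy().reset_index(drop=True)
    pred = np.full(len(out), np.nan)
    sites = out[["site_id", "x_km", "y_km"]].drop_duplicates("site_id")
    for sid, x, y in sites.itertuples(index=False):
        rows = out["site_id"] == sid
        own = int(regions.region_of(x, y))
        dists = regions.boundary_distance(x, y)
        use = [r for r in regions.region_ids if r == own or float(dists[r]) <= blend_buffer_km]
        missing = [r for r in use if r not in models]
        if missing:
            raise ValueError(
                f"sensor {sid} needs calibration model(s) for region(s) {missing}"
            )
        preds = [
            models[r].predict(
                x,
                y,
                out.loc[rows, "pm25"].to_numpy(),
                out.loc[rows, "rh"].to_numpy(),
                out.loc[rows, "temp_f"].to_numpy(),
            )
            for r in use
        ]
        pred[rows.to_numpy()] = np.mean(preds, axis=0)
    out["pm25"] = np.maximum(pred, 0.0)
    out["source"] = "lowcost_calibrated"
    return out


def select_for_training(calibrated: pd.DataFrame, threshold: float = 12.0) -> pd.DataFrame:
    """Keep calibrated sensor-days strictly above the concentration threshold.

    Only high calibrated values (above the 12 µg/m³ annual-standard default)
    supplement the reference network in model training; the strict inequality
    is deliberate and configurable.
    """
    if calibrated.empty:
        return calibrated.copy()
    return calibrated[calibrated["pm25"] > threshold].reset_index(drop=True)
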