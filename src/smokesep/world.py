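"""Synthetic study domain with known smoke/background truth.

This module builds a fully specified desk-scale world that statistically
resembles the inputs of a national smoke-PM2.5 attribution analysis:

* a daily gridded background PM2.5 field (baseline + season + smooth spatial
  random field + meteorology term),
* additive smoke concentration fields from discrete drifting fire events,
* satellite-style plume polygons with density classes drawn around each
  event's footprint,
* a pair of chemical-transport-model-like simulations (background-only and
  total) with multiplicative, spatially correlated error,
* urban-clustered population and static land covariates,
* reference-grade monitors (urban-biased placement) reporting hourly
  truth + noise, and dual-channel low-cost sensors with a positive gain and
  humidity/temperature-dependent bias.

Because the generator retains the background/smoke decomposition, downstream
estimates can be scored against truth (parameter recovery) rather than only
against held-out observations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import MultiPoint, Polygon

__all__ = [
    "GridSpec",
    "WorldConfig",
    "TruthFields",
    "SmokeEvent",
    "PlumePolygon",
    "CTMFields",
    "World",
    "generate_world",
    "emulate_ctm",
    "sample_observations",
    "smoke_kernel",
]


@dataclass(frozen=True)
class GridSpec:
    """Regular planar grid of square cells, indexed row-major (iy, ix).

    Coordinates are kilometres on a plane; cell centers sit at
    ``origin + (i + 0.5) * cell_km``. Days are 0-based integers grouped into
    ``n_years`` equal "years" of ``n_days / n_years`` days.
    """

    nx: int
    ny: int
    cell_km: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    n_days: int = 360
    n_years: int = 3

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1 or self.n_days < 1:
            raise ValueError("grid dimensions and n_days must be >= 1")
        if self.cell_km <= 0:
            raise ValueError("cell_km must be positive")
        if self.n_years < 1 or self.n_days % self.n_years != 0:
            raise ValueError("n_days must be a positive multiple of n_years")

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def days_per_year(self) -> int:
        return self.n_days // self.n_years

    @property
    def x_centers(self) -> np.ndarray:
        return self.origin[0] + (np.arange(self.nx) + 0.5) * self.cell_km

    @property
    def y_centers(self) -> np.ndarray:
        return self.origin[1] + (np.arange(self.ny) + 0.5) * self.cell_km

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of shape (ny, nx) with cell-center coordinates."""
        return np.meshgrid(self.x_centers, self.y_centers)

    def cell_centers(self) -> np.ndarray:
        """(n_cells, 2) row-major array of cell-center coordinates."""
        xx, yy = self.center_mesh()
        return np.column_stack([xx.ravel(), yy.ravel()])

    def cell_of(self, x: float | np.ndarray, y: float | np.ndarray):
        """Map coordinates to (iy, ix); raises for out-of-grid points."""
        ix = np.floor((np.asarray(x) - self.origin[0]) / self.cell_km).astype(int)
        iy = np.floor((np.asarray(y) - self.origin[1]) / self.cell_km).astype(int)
        bad = (ix < 0) | (ix >= self.nx) | (iy < 0) | (iy >= self.ny)
        if np.any(bad):
            raise ValueError(f"{int(np.sum(bad))} point(s) fall outside the grid")
        return iy, ix

    def cell_id(self, iy, ix) -> np.ndarray:
        return np.asarray(iy) * self.nx + np.asarray(ix)

    def year_of(self, date: np.ndarray) -> np.ndarray:
        return np.asarray(date) // self.days_per_year


@dataclass
class SmokeEvent:
    """A discrete fire event adding an exponential-kernel plume to the grid.

    On each active day the event center drifts by ``drift`` km/day and adds
    ``strength * exp(-distance / decay_km)`` to the smoke field.
    """

    center: tuple[float, float]
    start_day: int
    end_day: int
    strength: float
    decay_km: float
    drift: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.start_day > self.end_day:
            raise ValueError("start_day must be <= end_day")
        if self.strength <= 0 or self.decay_km <= 0:
            raise ValueError("strength and decay_km must be positive")

    def center_on(self, day: int) -> tuple[float, float]:
        k = day - self.start_day
        return (self.center[0] + k * self.drift[0], self.center[1] + k * self.drift[1])


def smoke_kernel(event: SmokeEvent, x: np.ndarray, y: np.ndarray, day: int) -> np.ndarray:
    """Smoke concentration added by ``event`` at points (x, y) on ``day``."""
    if not (event.start_day <= day <= event.end_day):
        return np.zeros(np.broadcast(x, y).shape)
    cx, cy = event.center_on(day)
    d = np.hypot(np.asarray(x) - cx, np.asarray(y) - cy)
    return event.strength * np.exp(-d / event.decay_km)


@dataclass
class PlumePolygon:
    """Satellite-style smoke plume: a simple polygon valid for one day.

    ``density_class`` follows the light/medium/heavy convention as integer
    codes 1/2/3; ``[start_hour, end_hour)`` is the observed overpass window.
    """

    date: int
    polygon: Polygon
    start_hour: int
    end_hour: int
    density_class: int

    def __post_init__(self) -> None:
        if not (0 <= self.start_hour < self.end_hour <= 24):
            raise ValueError("need 0 <= start_hour < end_hour <= 24")
        if self.density_class not in (1, 2, 3):
            raise ValueError("density_class must be 1, 2 or 3")
        if not self.polygon.is_valid or self.polygon.is_empty:
            raise ValueError("polygon ring must be simple and non-empty")

    @property
    def duration_hours(self) -> int:
        return self.end_hour - self.start_hour


@dataclass
class CTMFields:
    """Paired chemical-transport-model simulations on the study grid.

    ``background`` is the no-fire run, ``total`` the run with fire emissions;
    both are (n_days, ny, nx) in µg/m³ and satisfy total >= background >= 0.
    """

    background: np.ndarray
    total: np.ndarray

    def __post_init__(self) -> None:
        if self.background.shape != self.total.shape:
            raise ValueError("background and total must share a shape")
        if np.any(self.background < 0) or np.any(self.total < self.background - 1e-9):
            raise ValueError("need 0 <= background <= total")

    @property
    def smoke_ratio(self) -> np.ndarray:
        """Simulated smoke fraction of total PM2.5; 0 where total is 0."""
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (self.total - self.background) / self.total
        return np.where(self.total > 0, np.clip(r, 0.0, 1.0), 0.0)


@dataclass
class TruthFields:
    """Ground truth of the synthetic world.

    Daily fields are (n_days, ny, nx); population is (n_years, ny, nx);
    static covariates are (ny, nx). ``background`` and ``smoke`` are the
    quantities the separation pipeline tries to recover.
    """

    background: np.ndarray
    smoke: np.ndarray
    temp_f: np.ndarray
    rh: np.ndarray
    wind_u: np.ndarray
    wind_v: np.ndarray
    aod_true: np.ndarray
    cloud: np.ndarray
    population: np.ndarray
    elevation: np.ndarray
    frac_urban: np.ndarray
    frac_forest: np.ndarray
    road_km: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.background + self.smoke


@dataclass
class WorldConfig:
    """Parameters of the synthetic world.

    Defaults define the standard desk-scale study: a 50x50 grid of 1-km
    cells over three 120-day years, eight fire events per year, 45
    urban-biased reference monitors and 110 more dispersed dual-channel
    low-cost sensors with the documented positive humidity bias.
    """

    nx: int = 50
    ny: int = 50
    cell_km: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    days_per_year: int = 120
    n_years: int = 3

    # background field (µg/m³)
    background_mean: float = 8.0
    seasonal_amplitude: float = 3.0
    spatial_sd: float = 2.0
    spatial_corr_km: float = 10.0
    daily_sd: float = 1.5
    temp_coeff: float = 0.04  # µg/m³ per °F departure from 70 °F
    rh_coeff: float = 0.02  # µg/m³ per % RH departure from 50 %

    # fire events
    events_per_year: float = 8.0
    strength_log_mean: float = 3.0  # ln µg/m³ (median ≈ 20 µg/m³ peak)
    strength_log_sd: float = 0.6
    decay_km_min: float = 3.0
    decay_km_max: float = 10.0
    duration_min_days: int = 2
    duration_max_days: int = 8
    drift_km_per_day: float = 1.5
    plume_threshold: float = 2.0  # µg/m³ of event smoke that shows in imagery

    # population and statics
    n_urban_centers: int = 5
    population_total: float = 2.0e6
    population_growth: float = 0.01  # per year

    # satellite AOD; retrieval noise keeps AOD a weaker PM proxy than the
    # CTM runs, as in real column-vs-surface aerosol relationships
    aod_base: float = 0.08
    aod_pm_coeff: float = 0.015  # AOD per µg/m³ of total PM2.5
    aod_noise_sd: float = 0.06
    cloud_missing_threshold: float = 0.6  # cloud fraction above which AOD is lost

    # monitors and sensors
    n_reference: int = 45
    n_lowcost: int = 110
    reference_pop_exponent: float = 1.0  # placement prob ∝ population^γ
    lowcost_pop_exponent: float = 0.3
    reference_noise_sd: float = 1.0  # µg/m³, hourly
    lowcost_gain_bias: float = 0.35  # multiplicative over-reading
    lowcost_rh_coeff: float = 0.05  # µg/m³ per % RH
    lowcost_temp_coeff: float = 0.02  # µg/m³ per °F
    lowcost_noise_sd: float = 2.0  # µg/m³, hourly, per channel
    inject_qc_failures: bool = True
    qc_failure_rate: float = 0.01

    # CTM error
    ctm_sigma_background: float = 0.25  # sd of log-scale multiplicative error
    ctm_sigma_total: float = 0.25
    ctm_error_corr_km: float = 15.0
    ctm_run_correlation: float = 0.9  # error shared between the paired runs

    def grid(self) -> GridSpec:
        return GridSpec(
            nx=self.nx,
            ny=self.ny,
            cell_km=self.cell_km,
            origin=self.origin,
            n_days=self.days_per_year * self.n_years,
            n_years=self.n_years,
        )

    def with_updates(self, **kwargs) -> "WorldConfig":
        return replace(self, **kwargs)


@dataclass
class World:
    """Everything the downstream pipeline consumes, truth included.

    ``coarse_aod_xy`` / ``coarse_aod`` emulate a coarse-resolution reanalysis
    aerosol product: node coordinates (n_nodes, 2) and per-day node values
    (n_days, n_nodes), used to gap-fill the cloud-masked satellite AOD.
    """

    grid: GridSpec
    truth: TruthFields
    events: list[SmokeEvent]
    plumes: list[PlumePolygon]
    ctm: CTMFields
    reference_sites: pd.DataFrame
    lowcost_sites: pd.DataFrame
    reference_hourly: pd.DataFrame
    lowcost_hourly: pd.DataFrame
    coarse_aod_xy: np.ndarray
    coarse_aod: np.ndarray
    config: WorldConfig


# ---------------------------------------------------------------------------
# field helpers


def _smooth_field(rng: np.random.Generator, shape: tuple[int, ...], sigma_cells: float) -> np.ndarray:
    """Unit-variance Gaussian random field smoothed to the given scale."""
    z = rng.standard_normal(shape)
    if sigma_cells > 0:
        z = gaussian_filter(z, sigma=sigma_cells, mode="reflect")
    sd = z.std()
    return z / sd if sd > 0 else z


def _smooth_daily_fields(
    rng: np.random.Generator, n_days: int, ny: int, nx: int, sigma_cells: float, sigma_days: float
) -> np.ndarray:
    """(n_days, ny, nx) noise correlated in space and time, unit variance."""
    z = rng.standard_normal((n_days, ny, nx))
    z = gaussian_filter(z, sigma=(sigma_days, sigma_cells, sigma_cells), mode="reflect")
    sd = z.std()
    return z / sd if sd > 0 else z


def _seasonal(grid: GridSpec, phase: float = 0.0) -> np.ndarray:
    """Per-day seasonal sinusoid over the synthetic year, in [-1, 1]."""
    doy = np.arange(grid.n_days) % grid.days_per_year
    return np.sin(2 * np.pi * doy / grid.days_per_year + phase)


def _population(cfg: WorldConfig, grid: GridSpec, rng: np.random.Generator) -> np.ndarray:
    xx, yy = grid.center_mesh()
    dens = np.full((grid.ny, grid.nx), 0.05)
    for _ in range(cfg.n_urban_centers):
        cx = rng.uniform(grid.origin[0], grid.origin[0] + grid.nx * grid.cell_km)
        cy = rng.uniform(grid.origin[1], grid.origin[1] + grid.ny * grid.cell_km)
        scale = rng.uniform(2.0, 6.0)
        weight = rng.uniform(0.5, 2.0)
        dens += weight * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * scale**2))
    base = dens / dens.sum() * cfg.population_total
    years = np.arange(grid.n_years)
    return base[None, :, :] * (1.0 + cfg.population_growth) ** years[:, None, None]


def _draw_events(cfg: WorldConfig, grid: GridSpec, rng: np.random.Generator) -> list[SmokeEvent]:
    n_events = int(round(cfg.events_per_year * grid.n_years))
    events: list[SmokeEvent] = []
    x0, y0 = grid.origin
    for _ in range(n_events):
        start = int(rng.integers(0, grid.n_days))
        duration = int(rng.integers(cfg.duration_min_days, cfg.duration_max_days + 1))
        end = min(start + duration - 1, grid.n_days - 1)
        theta = rng.uniform(0, 2 * np.pi)
        speed = rng.uniform(0.2, 1.0) * cfg.drift_km_per_day
        events.append(
            SmokeEvent(
                center=(
                    rng.uniform(x0, x0 + grid.nx * grid.cell_km),
                    rng.uniform(y0, y0 + grid.ny * grid.cell_km),
                ),
                start_day=start,
                end_day=end,
                strength=float(np.exp(rng.normal(cfg.strength_log_mean, cfg.strength_log_sd))),
                decay_km=float(rng.uniform(cfg.decay_km_min, cfg.decay_km_max)),
                drift=(speed * math.cos(theta), speed * math.sin(theta)),
            )
        )
    return events


def _smoke_field_and_plumes(
    cfg: WorldConfig, grid: GridSpec, events: Sequence[SmokeEvent], rng: np.random.Generator
) -> tuple[np.ndarray, list[PlumePolygon]]:
    xx, yy = grid.center_mesh()
    smoke = np.zeros((grid.n_days, grid.ny, grid.nx))
    # raw (event, day) footprints from which polygons are drawn
    raw: list[tuple[int, np.ndarray, float]] = []
    for ev in events:
        for day in range(ev.start_day, ev.end_day + 1):
            f = smoke_kernel(ev, xx, yy, day)
            smoke[day] += f
            mask = f > cfg.plume_threshold
            if mask.any():
                raw.append((day, mask, float(f.max())))

    plumes: list[PlumePolygon] = []
    if raw:
        peaks = np.array([p for _, _, p in raw])
        q1, q2 = np.quantile(peaks, [1 / 3, 2 / 3])
        for day, mask, peak in raw:
            pts = MultiPoint(np.column_stack([xx[mask], yy[mask]]))
            poly = pts.convex_hull.buffer(0.6 * grid.cell_km, quad_segs=4)
            start_hour = int(rng.integers(6, 13))
            end_hour = min(start_hour + int(rng.integers(4, 11)), 24)
            plumes.append(
                PlumePolygon(
                    date=day,
                    polygon=poly,
                    start_hour=start_hour,
                    end_hour=end_hour,
                    density_class=int(1 + (peak > q1) + (peak > q2)),
                )
            )
    return smoke, plumes


def emulate_ctm(
    truth: TruthFields,
    grid: GridSpec,
    sigma_b: float = 0.25,
    sigma_t: float = 0.25,
    corr_km: float = 15.0,
    run_correlation: float = 0.9,
    seed: int = 0,
) -> CTMFields:
    """Emulate paired no-fire / with-fire model runs with multiplicative error.

    ``background_run = B * exp(ε_b)`` and ``total_run = (B + F) * exp(ε_t)``
    with spatially correlated zero-mean Gaussian ε of the given log-scale
    standard deviations; the total run is then floored at the background run
    so the smoke ratio stays in [0, 1]. The two runs share most of their
    error (same meteorology and non-fire emissions), so ε_b and ε_t are
    correlated with coefficient ``run_correlation``; with the default 0.9
    the smoke ratio stays small on truly smoke-free cell-days.
    """
    if sigma_b < 0 or sigma_t < 0:
        raise ValueError("sigma values must be >= 0")
    if not 0 <= run_correlation <= 1:
        raise ValueError("run_correlation must be in [0, 1]")
    rng = np.random.default_rng(seed)
    shape = truth.background.shape
    sigma_cells = corr_km / grid.cell_km / 2.0
    common = _smooth_daily_fields(rng, *shape, sigma_cells, 1.0)
    own_b = _smooth_daily_fields(rng, *shape, sigma_cells, 1.0)
    own_t = _smooth_daily_fields(rng, *shape, sigma_cells, 1.0)
    rho = math.sqrt(run_correlation)
    tau = math.sqrt(1.0 - run_correlation)
    eps_b = sigma_b * (rho * common + tau * own_b)
    eps_t = sigma_t * (rho * common + tau * own_t)
    background = truth.background * np.exp(eps_b)
    total = truth.total * np.exp(eps_t)
    return CTMFields(background=background, total=np.maximum(total, background))


def _place_sites(
    grid: GridSpec,
    population: np.ndarray,
    n_sites: int,
    pop_exponent: float,
    prefix: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Sample distinct cells with probability ∝ population^exponent."""
    if n_sites > grid.n_cells:
        raise ValueError("more sites than grid cells")
    w = np.power(np.maximum(population[0].ravel(), 1e-12), pop_exponent)
    idx = rng.choice(grid.n_cells, size=n_sites, replace=False, p=w / w.sum())
    iy, ix = np.divmod(idx, grid.nx)
    jitter = rng.uniform(-0.45, 0.45, size=(n_sites, 2)) * grid.cell_km
    x = grid.x_centers[ix] + jitter[:, 0]
    y = grid.y_centers[iy] + jitter[:, 1]
    return pd.DataFrame(
        {
            "site_id": [f"{prefix}{i:04d}" for i in range(n_sites)],
            "x_km": x,
            "y_km": y,
            "iy": iy,
            "ix": ix,
        }
    )


def sample_observations(
    truth: TruthFields,
    grid: GridSpec,
    reference_sites: pd.DataFrame,
    lowcost_sites: pd.DataFrame,
    cfg: WorldConfig,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw hourly monitor records from the truth fields.

    Reference monitors report hourly ``truth + N(0, σ_ref)`` floored at 0.
    Each low-cost channel reports
    ``truth * (1 + a) + b_rh * RH + b_t * T + noise`` — a positive gain and
    humidity/temperature bias typical of optical particle counters. When
    ``cfg.inject_qc_failures`` is set, a small fraction of sensor-days is
    degraded (15-hour days, divergent channels, out-of-range extremes) to
    exercise quality control.

    Returns ``(reference_hourly, lowcost_hourly)`` DataFrames.
    """
    rng = np.random.default_rng(seed)
    n_days = grid.n_days
    hours = np.arange(24)

    def site_daily(sites: pd.DataFrame, field: np.ndarray) -> np.ndarray:
        # (n_sites, n_days) of the per-cell daily field at each site's cell
        return field[:, sites["iy"].to_numpy(), sites["ix"].to_numpy()].T

    def expand_hourly(sites: pd.DataFrame, daily: np.ndarray) -> np.ndarray:
        return np.repeat(daily[:, :, None], 24, axis=2)

    # ---- reference monitors -------------------------------------------------
    n_ref = len(reference_sites)
    ref_truth = expand_hourly(reference_sites, site_daily(reference_sites, truth.total))
    ref_pm = np.maximum(ref_truth + rng.normal(0, cfg.reference_noise_sd, ref_truth.shape), 0.0)
    ref = pd.DataFrame(
        {
            "site_id": np.repeat(reference_sites["site_id"].to_numpy(), n_days * 24),
            "date": np.tile(np.repeat(np.arange(n_days), 24), n_ref),
            "hour": np.tile(hours, n_ref * n_days),
            "pm25": ref_pm.ravel(),
        }
    )

    # ---- low-cost sensors ---------------------------------------------------
    n_lc = len(lowcost_sites)
    lc_truth = expand_hourly(lowcost_sites, site_daily(lowcost_sites, truth.total))
    lc_rh = expand_hourly(lowcost_sites, site_daily(lowcost_sites, truth.rh))
    lc_temp = expand_hourly(lowcost_sites, site_daily(lowcost_sites, truth.temp_f))
    biased = (
        lc_truth * (1.0 + cfg.lowcost_gain_bias)
        + cfg.lowcost_rh_coeff * lc_rh
        + cfg.lowcost_temp_coeff * lc_temp
    )
    pm_a = np.maximum(biased + rng.normal(0, cfg.lowcost_noise_sd, biased.shape), 0.0)
    pm_b = np.maximum(biased + rng.normal(0, cfg.lowcost_noise_sd, biased.shape), 0.0)
    lc = pd.DataFrame(
        {
            "site_id": np.repeat(lowcost_sites["site_id"].to_numpy(), n_days * 24),
            "date": np.tile(np.repeat(np.arange(n_days), 24), n_lc),
            "hour": np.tile(hours, n_lc * n_days),
            "pm_a": pm_a.ravel(),
            "pm_b": pm_b.ravel(),
            "temp_f": lc_temp.ravel(),
            "rh": lc_rh.ravel(),
        }
    )

    if cfg.inject_qc_failures and n_lc > 0:
        lc = _degrade_sensor_days(lc, n_lc, n_days, cfg.qc_failure_rate, rng)

    return ref, lc


def _degrade_sensor_days(
    lc: pd.DataFrame, n_lc: int, n_days: int, rate: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Inject QC-failing sensor-days: short days, channel divergence, extremes."""
    n_bad = max(3, int(rate * n_lc * n_days))
    sensor_days = rng.choice(n_lc * n_days, size=min(3 * n_bad, n_lc * n_days), replace=False)
    short = sensor_days[:n_bad]
    diverge = sensor_days[n_bad : 2 * n_bad]
    extreme = sensor_days[2 * n_bad : 2 * n_bad + 3]

    # rows are ordered (sensor, day, hour); index arithmetic avoids a join
    key = np.arange(len(lc)) // 24
    drop = np.isin(key, short) & (lc["hour"].to_numpy() >= 15)  # keep exactly 15 hours
    div_rows = np.isin(key, diverge)
    lc.loc[div_rows, "pm_b"] = lc.loc[div_rows, "pm_b"] * 1.8 + 5.0
    ext_rows = np.isin(key, extreme)
    if ext_rows.any():
        uniq = np.unique(key[ext_rows])
        # one sensor-day each: absurd concentration, impossible RH, impossible temp
        modes = {uniq[i]: i % 3 for i in range(len(uniq))}
        for k, mode in modes.items():
            rows = key == k
            if mode == 0:
                lc.loc[rows, ["pm_a", "pm_b"]] = 1500.0
            elif mode == 1:
                lc.loc[rows, "rh"] = 105.0
            else:
                lc.loc[rows, "temp_f"] = 150.0
    return lc[~drop].reset_index(drop=True)


def generate_world(config: WorldConfig | None = None, seed: int = 0) -> World:
    """Generate the full synthetic study domain.

    The same ``(config, seed)`` pair always yields a bit-identical world.
    Returns a :class:`World` bundling truth fields, fire events, plume
    polygons, paired CTM runs, monitor/sensor site tables and hourly records.
    """
    cfg = config or WorldConfig()
    grid = cfg.grid()
    ss = np.random.SeedSequence(seed)
    (
        s_met,
        s_back,
        s_events,
        s_plumes,
        s_pop,
        s_static,
        s_aod,
        s_ctm,
        s_sites,
        s_obs,
    ) = [np.random.default_rng(c) for c in ss.spawn(10)]

    sigma_cells = cfg.spatial_corr_km / grid.cell_km / 2.0
    season = _seasonal(grid)[:, None, None]

    # meteorology
    temp_spatial = _smooth_field(s_met, (grid.ny, grid.nx), sigma_cells)
    temp_f = 70.0 + 15.0 * season + 6.0 * temp_spatial + 3.0 * _smooth_daily_fields(
        s_met, grid.n_days, grid.ny, grid.nx, sigma_cells, 2.0
    )
    rh = np.clip(
        55.0
        - 12.0 * season
        + 8.0 * _smooth_field(s_met, (grid.ny, grid.nx), sigma_cells)
        + 10.0 * _smooth_daily_fields(s_met, grid.n_days, grid.ny, grid.nx, sigma_cells, 2.0),
        0.0,
        100.0,
    )
    wind_u = 3.0 * _smooth_daily_fields(s_met, grid.n_days, grid.ny, grid.nx, sigma_cells, 1.0)
    wind_v = 3.0 * _smooth_daily_fields(s_met, grid.n_days, grid.ny, grid.nx, sigma_cells, 1.0)
    cloud = np.clip(
        0.4 + 0.35 * _smooth_daily_fields(s_met, grid.n_days, grid.ny, grid.nx, sigma_cells, 1.0),
        0.0,
        1.0,
    )

    # background = baseline + season + spatial field + daily term + meteorology
    background = np.maximum(
        cfg.background_mean
        + cfg.seasonal_amplitude * season
        + cfg.spatial_sd * _smooth_field(s_back, (grid.ny, grid.nx), sigma_cells)[None]
        + cfg.daily_sd * _smooth_daily_fields(s_back, grid.n_days, grid.ny, grid.nx, sigma_cells, 2.0)
        + cfg.temp_coeff * (temp_f - 70.0)
        + cfg.rh_coeff * (rh - 50.0),
        0.0,
    )

    events = _draw_events(cfg, grid, s_events)
    smoke, plumes = _smoke_field_and_plumes(cfg, grid, events, s_plumes)

    population = _population(cfg, grid, s_pop)
    elevation = 300.0 + 120.0 * _smooth_field(s_static, (grid.ny, grid.nx), sigma_cells)
    frac_urban = np.clip(
        population[0] / max(population[0].max(), 1e-12) * 0.9
        + 0.05 * _smooth_field(s_static, (grid.ny, grid.nx), sigma_cells),
        0.0,
        1.0,
    )
    frac_forest = np.clip(
        0.5 * (1 - frac_urban) + 0.2 * _smooth_field(s_static, (grid.ny, grid.nx), sigma_cells),
        0.0,
        1.0,
    )
    road_km = np.maximum(
        8.0 * frac_urban + 1.0 + 0.5 * s_static.standard_normal((grid.ny, grid.nx)), 0.0
    )

    total = background + smoke
    aod_true = np.maximum(
        cfg.aod_base
        + cfg.aod_pm_coeff * total
        + cfg.aod_noise_sd * _smooth_daily_fields(s_aod, grid.n_days, grid.ny, grid.nx, sigma_cells, 1.0),
        0.0,
    )

    truth = TruthFields(
        background=background,
        smoke=smoke,
        temp_f=temp_f,
        rh=rh,
        wind_u=wind_u,
        wind_v=wind_v,
        aod_true=aod_true,
        cloud=cloud,
        population=population,
        elevation=elevation,
        frac_urban=frac_urban,
        frac_forest=frac_forest,
        road_km=road_km,
    )

    ctm = emulate_ctm(
        truth,
        grid,
        sigma_b=cfg.ctm_sigma_background,
        sigma_t=cfg.ctm_sigma_total,
        corr_km=cfg.ctm_error_corr_km,
        run_correlation=cfg.ctm_run_correlation,
        seed=s_ctm.integers(2**31),
    )

    reference_sites = _place_sites(
        grid, population, cfg.n_reference, cfg.reference_pop_exponent, "aqs-", s_sites
    )
    lowcost_sites = _place_sites(
        grid, population, cfg.n_lowcost, cfg.lowcost_pop_exponent, "lcs-", s_sites
    )
    ref_hourly, lc_hourly = sample_observations(
        truth, grid, reference_sites, lowcost_sites, cfg, seed=s_obs.integers(2**31)
    )

    # coarse reanalysis-style AOD: true AOD sampled every 5 cells with
    # multiplicative error, to be regridded and used for gap-filling
    stride = max(1, min(5, grid.nx, grid.ny))
    cy, cx = np.meshgrid(
        np.arange(stride // 2, grid.ny, stride), np.arange(stride // 2, grid.nx, stride),
        indexing="ij",
    )
    coarse_xy = np.column_stack([grid.x_centers[cx.ravel()], grid.y_centers[cy.ravel()]])
    coarse_vals = truth.aod_true[:, cy.ravel(), cx.ravel()] * np.exp(
        s_aod.normal(0.0, 0.1, size=(grid.n_days, coarse_xy.shape[0]))
    )

    return World(
        coarse_aod_xy=coarse_xy,
        coarse_aod=coarse_vals,
        grid=grid,
        truth=truth,
        events=events,
        plumes=plumes,
        ctm=ctm,
        reference_sites=reference_sites,
        lowcost_sites=lowcost_sites,
        reference_hourly=ref_hourly,
        lowcost_hourly=lc_hourly,
        config=cfg,
    )
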