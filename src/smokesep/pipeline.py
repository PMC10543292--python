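"""End-to-end pipeline driver.

Runs simulate → calibrate → integrate → train → predict → evaluate →
metrics on one run directory, persisting each stage's outputs so stages can
also be re-run individually from disk. A manifest records the config, the
per-stage seeds fanned out from the global seed, library versions and row
counts.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import (
    RegionPartition,
    aggregate_reference,
    calibrate,
    fit_regional_gwr,
    pair_sensors,
    qc_daily_aggregate,
    select_for_training,
)
from .config import PipelineConfig, stage_seeds
from .evaluation import aggregate_cv, cross_validate
from .exposure import (
    design_values,
    monitor_impact_fraction,
    nonattainment,
    population_exposure_summary,
    smoke_impact_days,
    summarize_years,
    vicinity_mask,
)
from .integration import BACKGROUND_FEATURES, SMOKE_FEATURES, build_feature_table
from .io import (
    read_fields_netcdf,
    read_observations,
    read_plumes_geojson,
    write_fields_netcdf,
    write_json,
    write_observations,
    write_plumes_geojson,
)
from .separation import SeparationModel, predict_smoke, train
from .world import CTMFields, SmokeEvent, TruthFields, World, generate_world

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"] + [
    f"stage_{s}" for s in ("simulate", "calibrate", "integrate", "train", "predict", "evaluate", "metrics")
]


@dataclass
class PipelineResult:
    """In-memory handles to every stage product of one run."""

    config: PipelineConfig
    run_dir: Path
    world: World
    observations: pd.DataFrame
    calibration_metrics: dict
    smoke_table: pd.DataFrame
    background_table: pd.DataFrame
    model: SeparationModel
    estimates: pd.DataFrame
    smoke_field: np.ndarray
    total_field: np.ndarray
    cv: dict
    metrics: dict
    manifest: dict


def _dir(run_dir: str | Path, sub: str) -> Path:
    p = Path(run_dir) / sub
    p.mkdir(parents=True, exist_ok=True)
    return p


# ---------------------------------------------------------------------- stages


def stage_simulate(cfg: PipelineConfig, run_dir: str | Path) -> World:
    """Generate the synthetic world and persist it under ``world/``."""
    seed = stage_seeds(cfg.seed)["simulate"]
    world = generate_world(cfg.world, seed=seed)
    out = _dir(run_dir, "world")
    t = world.truth
    write_fields_netcdf(
        {
            "background": t.background,
            "smoke": t.smoke,
            "temp_f": t.temp_f,
            "rh": t.rh,
            "wind_u": t.wind_u,
            "wind_v": t.wind_v,
            "aod_true": t.aod_true,
            "cloud": t.cloud,
            "population": t.population,
            "elevation": t.elevation,
            "frac_urban": t.frac_urban,
            "frac_forest": t.frac_forest,
            "road_km": t.road_km,
            "ctm_background": world.ctm.background,
            "ctm_total": world.ctm.total,
            "coarse_aod": world.coarse_aod,
            "coarse_aod_xy": world.coarse_aod_xy,
        },
        out / "fields.nc",
    )
    write_plumes_geojson(world.plumes, out / "plumes.geojson")
    world.reference_sites.to_csv(out / "reference_sites.csv", index=False)
    world.lowcost_sites.to_csv(out / "lowcost_sites.csv", index=False)
    world.reference_hourly.to_csv(out / "reference_hourly.csv", index=False)
    world.lowcost_hourly.to_csv(out / "lowcost_hourly.csv", index=False)
    pd.DataFrame(
        [
            {
                "center_x": e.center[0],
                "center_y": e.center[1],
                "start_day": e.start_day,
                "end_day": e.end_day,
                "strength": e.strength,
                "decay_km": e.decay_km,
                "drift_x": e.drift[0],
                "drift_y": e.drift[1],
            }
            for e in world.events
        ]
    ).to_csv(out / "events.csv", index=False)
    return world


def load_world(cfg: PipelineConfig, run_dir: str | Path) -> World:
    """Reload a persisted world from ``run_dir/world``."""
    out = Path(run_dir) / "world"
    f = read_fields_netcdf(out / "fields.nc")
    truth = TruthFields(
        background=f["background"],
        smoke=f["smoke"],
        temp_f=f["temp_f"],
        rh=f["rh"],
        wind_u=f["wind_u"],
        wind_v=f["wind_v"],
        aod_true=f["aod_true"],
        cloud=f["cloud"],
        population=f["population"],
        elevation=f["elevation"],
        frac_urban=f["frac_urban"],
        frac_forest=f["frac_forest"],
        road_km=f["road_km"],
    )
    ctm = CTMFields(background=f["ctm_background"], total=f["ctm_total"])
    events = [
        SmokeEvent(
            center=(r.center_x, r.center_y),
            start_day=int(r.start_day),
            end_day=int(r.end_day),
            strength=r.strength,
            decay_km=r.decay_km,
            drift=(r.drift_x, r.drift_y),
        )
        for r in pd.read_csv(out / "events.csv").itertuples()
    ]
    return World(
        grid=cfg.world.grid(),
        truth=truth,
        events=events,
        plumes=read_plumes_geojson(out / "plumes.geojson"),
        ctm=ctm,
        reference_sites=pd.read_csv(out / "reference_sites.csv"),
        lowcost_sites=pd.read_csv(out / "lowcost_sites.csv"),
        reference_hourly=pd.read_csv(out / "reference_hourly.csv"),
        lowcost_hourly=pd.read_csv(out / "lowcost_hourly.csv"),
        coarse_aod_xy=f["coarse_aod_xy"],
        coarse_aod=f["coarse_aod"],
        config=cfg.world,
    )


def stage_calibrate(
    cfg: PipelineConfig, run_dir: str | Path, world: World | None = None
) -> tuple[pd.DataFrame, dict]:
    """QC, pair, calibrate and select sensor data; returns (observations, metrics).

    ``observations`` is the union of reference daily values and selected
    calibrated low-cost values, ready for cell assignment. The metrics dict
    reports the raw vs calibrated RMSE against paired references on
    held-out pairs (even sensor indices train, odd test).
    """
    world = world or load_world(cfg, run_dir)
    out = _dir(run_dir, "calibration")
    regions = RegionPartition.quadrants(world.grid)

    reference_daily = aggregate_reference(
        world.reference_hourly, min_hours=cfg.min_hours, sites=world.reference_sites
    )
    lowcost_raw = qc_daily_aggregate(
        world.lowcost_hourly, rules=cfg.qc_rules(), sites=world.lowcost_sites
    )
    pairs = pair_sensors(lowcost_raw, reference_daily, radius_km=cfg.pair_radius_km)

    # held-out split by sensor for the calibration-efficacy metric
    sensors = np.sort(pairs["site_id"].unique())
    train_ids = set(sensors[::2])
    pairs_train = pairs[pairs["site_id"].isin(train_ids)]
    pairs_test = pairs[~pairs["site_id"].isin(train_ids)]

    models = fit_regional_gwr(pairs, regions, bandwidth_km=cfg.gwr_bandwidth_km, kernel=cfg.gwr_kernel)
    calibrated = calibrate(lowcost_raw, models, regions, blend_buffer_km=cfg.blend_buffer_km)
    selected = select_for_training(calibrated, threshold=cfg.training_threshold)

    metrics = {"n_pairs": int(len(pairs)), "n_selected": int(len(selected))}
    if not pairs_test.empty and len(pairs_train) >= 25:
        held_models = fit_regional_gwr(
            pairs_train, regions, bandwidth_km=cfg.gwr_bandwidth_km, kernel=cfg.gwr_kernel
        )
        test_obs = pairs_test.rename(columns={"raw_pm25": "pm25"})[
            ["site_id", "x_km", "y_km", "date", "pm25", "rh", "temp_f"]
        ].assign(source="lowcost_raw")
        try:
            cal_test = calibrate(test_obs, held_models, regions, blend_buffer_km=cfg.blend_buffer_km)
            ref = pairs_test["ref_pm25"].to_numpy()
            metrics["rmse_raw"] = float(
                np.sqrt(np.mean((pairs_test["raw_pm25"].to_numpy() - ref) ** 2))
            )
            metrics["rmse_calibrated"] = float(
                np.sqrt(np.mean((cal_test["pm25"].to_numpy() - ref) ** 2))
            )
        except ValueError as e:  # a test sensor may need a region with no held-out model
            logger.warning("held-out calibration metric skipped: %s", e)

    observations = pd.concat([reference_daily, selected], ignore_index=True)
    write_observations(reference_daily, out / "reference_daily.csv")
    write_observations(lowcost_raw, out / "lowcost_raw.csv")
    pairs.to_csv(out / "pairs.csv", index=False)
    write_observations(calibrated, out / "calibrated.csv")
    write_observations(selected, out / "selected.csv")
    write_observations(observations, out / "observations.csv")
    write_json(metrics, out / "metrics.json")
    return observations, metrics


def stage_integrate(
    cfg: PipelineConfig,
    run_dir: str | Path,
    world: World | None = None,
    observations: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build and persist the smoke / no-smoke feature tables."""
    world = world or load_world(cfg, run_dir)
    if observations is None:
        observations = read_observations(Path(run_dir) / "calibration" / "observations.csv")
    out = _dir(run_dir, "integration")
    smoke_table, background_table = build_feature_table(
        world,
        observations,
        ratio_threshold=cfg.ratio_threshold,
        idw_power=cfg.idw_power,
        idw_k=cfg.idw_k,
    )
    smoke_table.to_parquet(out / "smoke_table.parquet", index=False)
    background_table.to_parquet(out / "background_table.parquet", index=False)
    return smoke_table, background_table


def _load_tables(run_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    out = Path(run_dir) / "integration"
    return (
        pd.read_parquet(out / "smoke_table.parquet"),
        pd.read_parquet(out / "background_table.parquet"),
    )


def stage_train(
    cfg: PipelineConfig,
    run_dir: str | Path,
    tables: tuple[pd.DataFrame, pd.DataFrame] | None = None,
) -> SeparationModel:
    smoke_table, background_table = tables or _load_tables(run_dir)
    seed = stage_seeds(cfg.seed)["train"]
    model = train(
        smoke_table,
        background_table,
        rf_params=cfg.rf_params(),
        smote_params=cfg.smote_params(),
        seed=seed,
    )
    model.save(_dir(run_dir, "model") / "model.bin")
    return model


def stage_predict(
    cfg: PipelineConfig,
    run_dir: str | Path,
    model: SeparationModel | None = None,
    tables: tuple[pd.DataFrame, pd.DataFrame] | None = None,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Predict smoke on smoke-labeled cell-days and assemble national fields.

    Returns ``(estimates, smoke_field, total_field)``: the smoke field is 0
    on no-smoke cell-days; the total field is the background prediction
    there and the total-model prediction on smoke cell-days.
    """
    smoke_table, background_table = tables or _load_tables(run_dir)
    model = model or SeparationModel.load(Path(run_dir) / "model" / "model.bin")
    out = _dir(run_dir, "model")
    grid = cfg.world.grid()

    estimates = predict_smoke(model, smoke_table)
    estimates.to_csv(out / "estimates.csv", index=False)

    smoke_field = np.zeros((grid.n_days, grid.ny, grid.nx))
    total_field = np.zeros_like(smoke_field)
    d = estimates["date"].to_numpy()
    iy = estimates["iy"].to_numpy()
    ix = estimates["ix"].to_numpy()
    smoke_field[d, iy, ix] = estimates["smoke_pred"].to_numpy()
    total_field[d, iy, ix] = estimates["total_pred"].to_numpy()

    back_pred = model.f_background.predict(background_table[model.background_features])
    total_field[
        background_table["date"].to_numpy(),
        background_table["iy"].to_numpy(),
        background_table["ix"].to_numpy(),
    ] = back_pred

    write_fields_netcdf({"smoke_pred": smoke_field, "total_pred": total_field}, out / "fields_pred.nc")
    return estimates, smoke_field, total_field


def stage_evaluate(
    cfg: PipelineConfig,
    run_dir: str | Path,
    tables: tuple[pd.DataFrame, pd.DataFrame] | None = None,
) -> dict:
    """Cross-validate both models under the configured schemes."""
    smoke_table, background_table = tables or _load_tables(run_dir)
    out = _dir(run_dir, "evaluation")
    seed = stage_seeds(cfg.seed)["evaluate"]
    grid = cfg.world.grid()
    results: dict = {}
    for name, table, feats in (
        ("smoke", smoke_table, SMOKE_FEATURES),
        ("background", background_table, BACKGROUND_FEATURES),
    ):
        for scheme in cfg.cv_schemes:
            cv = cross_validate(
                table,
                feats,
                scheme=scheme,
                k=cfg.cv_folds,
                seed=seed,
                rf_params=cfg.rf_params(),
                smote_params=cfg.smote_params(),
            )
            monthly_r2, _ = aggregate_cv(
                cv.predictions, "monthly", days_per_year=grid.days_per_year
            )
            annual_r2, _ = aggregate_cv(
                cv.predictions, "annual", days_per_year=grid.days_per_year
            )
            results[f"{name}_{scheme}"] = {
                "r2": cv.r2,
                "rmse": cv.rmse,
                "monthly_r2": monthly_r2,
                "annual_r2": annual_r2,
                "n": int(len(cv.predictions)),
            }
            cv.predictions.to_csv(out / f"oof_{name}_{scheme}.csv", index=False)
    write_json(results, out / "cv_summary.json")
    return results


def stage_metrics(
    cfg: PipelineConfig,
    run_dir: str | Path,
    world: World | None = None,
    fields: tuple[np.ndarray, np.ndarray] | None = None,
) -> dict:
    """Exposure and attainment metrics from the predicted fields."""
    world = world or load_world(cfg, run_dir)
    if fields is None:
        f = read_fields_netcdf(Path(run_dir) / "model" / "fields_pred.nc")
        smoke_field, total_field = f["smoke_pred"], f["total_pred"]
    else:
        smoke_field, total_field = fields
    out = _dir(run_dir, "metrics")
    grid = world.grid

    counts = smoke_impact_days(
        smoke_field, total_field, grid.days_per_year, share_threshold=cfg.share_threshold
    )
    mon_iy = world.reference_sites["iy"].to_numpy()
    mon_ix = world.reference_sites["ix"].to_numpy()
    impact_fraction = monitor_impact_fraction(counts, mon_iy, mon_ix, min_days=cfg.min_impact_days)
    mask = vicinity_mask(
        world.reference_sites["x_km"].to_numpy(),
        world.reference_sites["y_km"].to_numpy(),
        grid,
        radius_km=cfg.vicinity_km,
    )
    exposure = population_exposure_summary(
        smoke_field,
        total_field,
        counts,
        world.truth.population,
        mask,
        grid.days_per_year,
        pop_scale=1e6,
    )
    summary = summarize_years(exposure)

    n_years = grid.n_years
    shape = (n_years, grid.days_per_year, grid.ny, grid.nx)
    annual_total = total_field.reshape(shape).mean(axis=1)
    annual_background = (total_field - smoke_field).reshape(shape).mean(axis=1)
    attainment = []
    if n_years >= cfg.dv_window:
        dv_with = design_values(annual_total, window=cfg.dv_window)
        dv_without = design_values(annual_background, window=cfg.dv_window)
        for j in range(dv_with.shape[0]):
            year = cfg.dv_window - 1 + j
            for thr in cfg.naaqs:
                for scen, dv in (("with_smoke", dv_with[j]), ("without_smoke", dv_without[j])):
                    r = nonattainment(
                        dv, thr, scen, world.truth.population[year], mon_iy, mon_ix, year=year
                    )
                    attainment.append(r.__dict__)

    exposure.to_csv(out / "exposure_by_year.csv", index=False)
    pd.DataFrame(attainment).to_csv(out / "attainment.csv", index=False)
    metrics = {
        "monitor_impact_fraction_by_year": impact_fraction.tolist(),
        "exposure_summary": summary,
        "attainment": attainment,
    }
    write_json(metrics, out / "summary.json")
    return metrics


# ---------------------------------------------------------------------- driver


def run_pipeline(cfg: PipelineConfig, run_dir: str | Path) -> PipelineResult:
    """Execute all stages on a run directory and write the manifest.

    Any stage failure is re-raised with the stage name attached.
    """
    cfg.validate()
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(run_dir / "config.yaml")
    seeds = stage_seeds(cfg.seed)
    manifest: dict = {
        "smokesep_version": __version__,
        "numpy_version": np.__version__,
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(
            (run_dir / "config.yaml").read_bytes()
        ).hexdigest(),
        "seed": cfg.seed,
        "stage_seeds": seeds,
        "stages": [],
    }

    state: dict = {}

    def _run(name, fn):
        logger.info("stage %s ...", name)
        try:
            result = fn()
        except Exception as e:
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        manifest["stages"].append(name)
        return result

    state["world"] = _run("simulate", lambda: stage_simulate(cfg, run_dir))
    state["observations"], state["cal_metrics"] = _run(
        "calibrate", lambda: stage_calibrate(cfg, run_dir, state["world"])
    )
    state["tables"] = _run(
        "integrate",
        lambda: stage_integrate(cfg, run_dir, state["world"], state["observations"]),
    )
    state["model"] = _run("train", lambda: stage_train(cfg, run_dir, state["tables"]))
    state["estimates"], state["smoke_field"], state["total_field"] = _run(
        "predict", lambda: stage_predict(cfg, run_dir, state["model"], state["tables"])
    )
    state["cv"] = _run("evaluate", lambda: stage_evaluate(cfg, run_dir, state["tables"]))
    state["metrics"] = _run(
        "metrics",
        lambda: stage_metrics(
            cfg, run_dir, state["world"], (state["smoke_field"], state["total_field"])
        ),
    )

    smoke_table, background_table = state["tables"]
    manifest["row_counts"] = {
        "smoke_table": int(len(smoke_table)),
        "background_table": int(len(background_table)),
        "smoke_observed": int(smoke_table["obs_pm25"].notna().sum()),
        "background_observed": int(background_table["obs_pm25"].notna().sum()),
        "estimates": int(len(state["estimates"])),
    }
    manifest["calibration_metrics"] = state["cal_metrics"]
    manifest["oversampled_fraction"] = state["model"].oversampled_fraction
    manifest["negative_difference_count"] = state["model"].n_negative_differences
    write_json(manifest, run_dir / "manifest.json")

    return PipelineResult(
        config=cfg,
        run_dir=run_dir,
        world=state["world"],
        observations=state["observations"],
        calibration_metrics=state["cal_metrics"],
        smoke_table=smoke_table,
        background_table=background_table,
        model=state["model"],
        estimates=state["estimates"],
        smoke_field=state["smoke_field"],
        total_field=state["total_field"],
        cv=state["cv"],
        metrics=state["metrics"],
        manifest=manifest,
    )
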