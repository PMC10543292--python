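"""Shared fixtures.

Heavy products of the default synthetic study (world, calibrated
observations, feature tables, trained model, smoke estimates) are built once
per session and shared by the acceptance-level tests; unit tests use small
purpose-built worlds instead.
"""

from __future__ import annotations

import numpy as np
import pytest

import smokesep as ss


TINY = ss.WorldConfig(
    nx=20,
    ny=20,
    days_per_year=30,
    n_years=2,
    n_reference=12,
    n_lowcost=25,
    events_per_year=4,
)


@pytest.fixture(scope="session")
def tiny_world() -> ss.World:
    return ss.generate_world(TINY, seed=11)


@pytest.fixture(scope="session")
def default_config() -> ss.PipelineConfig:
    return ss.PipelineConfig().validate()


@pytest.fixture(scope="session")
def default_world(default_config) -> ss.World:
    seed = ss.stage_seeds(default_config.seed)["simulate"]
    return ss.generate_world(default_config.world, seed=seed)


@pytest.fixture(scope="session")
def default_calibration(default_config, default_world, tmp_path_factory):
    """(observations, metrics) of the calibration stage on the default world."""
    from smokesep.pipeline import stage_calibrate

    run_dir = tmp_path_factory.mktemp("default_run")
    return stage_calibrate(default_config, run_dir, default_world)


@pytest.fixture(scope="session")
def default_tables(default_config, default_world, default_calibration):
    observations, _ = default_calibration
    return ss.build_feature_table(
        default_world,
        observations,
        ratio_threshold=default_config.ratio_threshold,
        idw_power=default_config.idw_power,
        idw_k=default_config.idw_k,
    )


@pytest.fixture(scope="session")
def default_model(default_config, default_tables):
    smoke_table, background_table = default_tables
    seed = ss.stage_seeds(default_config.seed)["train"]
    return ss.train(
        smoke_table,
        background_table,
        rf_params=default_config.rf_params(),
        smote_params=default_config.smote_params(),
        seed=seed,
    )


@pytest.fixture(scope="session")
def default_estimates(default_model, default_tables):
    smoke_table, _ = default_tables
    return ss.predict_smoke(default_model, smoke_table)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
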