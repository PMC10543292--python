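"""Pipeline configuration: every threshold in one auditable place.

All numeric constants of the workflow — QC completeness and channel rules,
pairing radius, blend buffer, training threshold, smoke-ratio labeling
threshold, SMOTE strata, CV fold count, impact-day share, vicinity radius,
design-value window and candidate standards — live in
:class:`PipelineConfig` with their defaults, round-trip through YAML, and
are echoed into the run manifest.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .calibration import QCRules
from .separation import RFParams, SmoteParams
from .world import WorldConfig

STAGES = ("simulate", "calibrate", "integrate", "train", "predict", "evaluate", "metrics")

__all__ = ["STAGES", "PipelineConfig", "stage_seeds"]


@dataclass
class PipelineConfig:
    world: WorldConfig = field(default_factory=WorldConfig)

    # calibration
    min_hours: int = 16
    max_channel_rel_diff: float = 0.30
    max_daily_pm25: float = 1000.0
    temp_min_f: float = -20.0
    temp_max_f: float = 140.0
    rh_min: float = 0.0
    rh_max: float = 100.0
    pair_radius_km: float = 5.0
    gwr_bandwidth_km: float = 15.0
    gwr_kernel: str = "gaussian"
    blend_buffer_km: float = 20.0
    training_threshold: float = 12.0

    # integration
    ratio_threshold: float = 0.03
    idw_power: float = 2.0
    idw_k: int = 4

    # separation model
    smote_lo: float = 35.0
    smote_hi: float = 100.0
    smote_k: int = 5
    n_trees: int = 300
    min_leaf: int = 3
    max_features: str = "third"

    # evaluation
    cv_folds: int = 20
    cv_schemes: tuple[str, ...] = ("overall",)

    # exposure metrics
    share_threshold: float = 0.25
    vicinity_km: float = 5.0
    min_impact_days: int = 30
    dv_window: int = 3
    naaqs: tuple[float, ...] = (9.0, 10.0)

    seed: int = 17

    # ------------------------------------------------------------------ views
    def qc_rules(self) -> QCRules:
        return QCRules(
            min_hours=self.min_hours,
            max_channel_rel_diff=self.max_channel_rel_diff,
            max_daily_pm25=self.max_daily_pm25,
            temp_min_f=self.temp_min_f,
            temp_max_f=self.temp_max_f,
            rh_min=self.rh_min,
            rh_max=self.rh_max,
        )

    def rf_params(self) -> RFParams:
        return RFParams(n_trees=self.n_trees, max_features=self.max_features, min_leaf=self.min_leaf)

    def smote_params(self) -> SmoteParams:
        return SmoteParams(lo=self.smote_lo, hi=self.smote_hi, k=self.smote_k)

    # ------------------------------------------------------------- validation
    def validate(self) -> "PipelineConfig":
        """Raise ValueError on any out-of-range setting; return self."""
        checks = [
            (self.min_hours >= 1 and self.min_hours <= 24, "min_hours must be in 1..24"),
            (0 < self.max_channel_rel_diff, "max_channel_rel_diff must be positive"),
            (self.pair_radius_km > 0, "pair_radius_km must be positive"),
            (self.gwr_bandwidth_km > 0, "gwr_bandwidth_km must be positive"),
            (self.blend_buffer_km >= 0, "blend_buffer_km must be >= 0"),
            (0 <= self.ratio_threshold <= 1, "ratio_threshold must be in [0, 1]"),
            (self.idw_power > 0 and self.idw_k >= 1, "idw_power > 0 and idw_k >= 1 required"),
            (0 < self.smote_lo < self.smote_hi, "need 0 < smote_lo < smote_hi"),
            (self.smote_k >= 1, "smote_k must be >= 1"),
            (self.n_trees >= 1 and self.min_leaf >= 1, "forest sizes must be >= 1"),
            (self.cv_folds >= 2, "cv_folds must be >= 2"),
            (all(s in ("overall", "spatial", "temporal") for s in self.cv_schemes), "unknown CV scheme"),
            (0 < self.share_threshold < 1, "share_threshold must be in (0, 1)"),
            (self.vicinity_km > 0, "vicinity_km must be positive"),
            (self.min_impact_days >= 1, "min_impact_days must be >= 1"),
            (self.dv_window >= 1, "dv_window must be >= 1"),
            (all(t > 0 for t in self.naaqs), "standards must be positive"),
            (self.world.nx >= 1 and self.world.ny >= 1, "grid dimensions must be >= 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: {msg}")
        return self

    # ---------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        d = asdict(self)
        d["world"]["origin"] = list(self.world.origin)
        d["cv_schemes"] = list(self.cv_schemes)
        d["naaqs"] = list(self.naaqs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        w = dict(d.pop("world", {}))
        if "origin" in w:
            w["origin"] = tuple(w["origin"])
        cfg = cls(world=WorldConfig(**w), **d)
        cfg = replace(
            cfg,
            cv_schemes=tuple(cfg.cv_schemes),
            naaqs=tuple(float(t) for t in cfg.naaqs),
        )
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def stage_seeds(seed: int) -> dict[str, int]:
    """Fan a global seed out to one independent sub-seed per stage.

    Stage i gets ``SeedSequence(seed, spawn_key=(i,))`` reduced below 2^31,
    so each stage is reproducible in isolation.
    """
    return {
        name: int(np.random.SeedSequence(seed, spawn_key=(i,)).generate_state(1)[0] % 2**31)
        for i, name in enumerate(STAGES)
    }
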