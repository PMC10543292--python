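"""Dual random-forest separation of smoke and background PM2.5.

Two regressors are trained independently: a background model on no-smoke
cell-days (no-fire CTM run + shared covariates) and a total model on
smoke-impacted cell-days (with-fire CTM run + shared covariates + plume
features). Smoke PM2.5 is attributed by difference — predicted total minus
predicted background — floored at zero, with the count of negative raw
differences kept as a diagnostic.

Because high concentrations are rare in monitor data, the training tables
are augmented with a regression extension of SMOTE: synthetic rows are
linear interpolations (features and target jointly) between a parent row and
one of its k nearest neighbours within the same high-concentration stratum.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.neighbors import NearestNeighbors

from .integration import BACKGROUND_FEATURES, SMOKE_FEATURES

logger = logging.getLogger(__name__)

__all__ = [
    "RFParams",
    "SmoteParams",
    "SeparationModel",
    "smote_augment",
    "train",
    "predict_smoke",
]


@dataclass(frozen=True)
class RFParams:
    """Random-forest hyperparameters (exposed, not tuned per run).

    ``max_features='third'`` uses ceil(p/3) candidate features per split,
    the classic regression-forest default.
    """

    n_trees: int = 300
    max_features: str | float = "third"
    min_leaf: int = 3

    def make(self, n_features: int, seed: int) -> RandomForestRegressor:
        mf = (
            int(np.ceil(n_features / 3))
            if self.max_features == "third"
            else self.max_features
        )
        return RandomForestRegressor(
            n_estimators=self.n_trees,
            max_features=mf,
            min_samples_leaf=self.min_leaf,
            random_state=seed,
            n_jobs=1,
        )


@dataclass(frozen=True)
class SmoteParams:
    """Oversampling thresholds: once in (lo, hi), twice above hi (µg/m³)."""

    lo: float = 35.0
    hi: float = 100.0
    k: int = 5

    def copies(self, target: np.ndarray) -> np.ndarray:
        return np.where(target > self.hi, 2, np.where(target > self.lo, 1, 0))


def smote_augment(
    rows: pd.DataFrame,
    feature_cols: list[str],
    target_col: str = "obs_pm25",
    params: SmoteParams = SmoteParams(),
    seed: int = 0,
) -> pd.DataFrame:
    """Oversample high-concentration rows by stratum-wise interpolation.

    Rows with target strictly in ``(lo, hi)`` gain one synthetic copy, rows
    strictly above ``hi`` gain two, so the output has exactly
    ``n + n_(lo,hi) + 2*n_(>hi)`` rows. A synthetic row is
    ``parent + u * (neighbour - parent)`` with ``u ~ U(0,1)`` applied to the
    features and the target jointly, the neighbour drawn uniformly from the
    parent's ``k`` nearest same-stratum rows in standardized feature space.
    One-member strata are duplicated verbatim with a warning.
    """
    if params.k < 1:
        raise ValueError("k must be >= 1")
    if rows.empty:
        return rows.copy()
    target = rows[target_col].to_numpy(float)
    copies = params.copies(target)
    if copies.sum() == 0:
        return rows.copy()

    rng = np.random.default_rng(seed)
    pieces = [rows]
    for n_copies, mask in ((1, copies == 1), (2, copies == 2)):
        if not mask.any():
            continue
        stratum = rows[mask].reset_index(drop=True)
        X = stratum[feature_cols].to_numpy(float)
        y = stratum[target_col].to_numpy(float)
        if len(stratum) == 1:
            warnings.warn("single-member SMOTE stratum duplicated, not interpolated")
            pieces.extend([stratum] * n_copies)
            continue
        sd = X.std(axis=0)
        Xs = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        k_eff = min(params.k, len(stratum) - 1)
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xs)
        neigh = nn.kneighbors(Xs, return_distance=False)[:, 1:]  # drop self
        for _ in range(n_copies):
            pick = neigh[np.arange(len(stratum)), rng.integers(0, k_eff, len(stratum))]
            u = rng.uniform(0.0, 1.0, len(stratum))
            synth = stratum.copy()
            synth[feature_cols] = X + u[:, None] * (X[pick] - X)
            synth[target_col] = y + u * (y[pick] - y)
            pieces.append(synth)
    out = pd.concat(pieces, ignore_index=True)
    return out


@dataclass
class SeparationModel:
    """Trained pair of regressors plus their feature lists and diagnostics."""

    f_background: RandomForestRegressor
    f_total: RandomForestRegressor
    background_features: list[str]
    smoke_features: list[str]
    rf_params: RFParams
    smote_params: SmoteParams
    seed: int
    importances_background: pd.Series = field(default_factory=pd.Series)
    importances_total: pd.Series = field(default_factory=pd.Series)
    oversampled_fraction: float = 0.0
    n_negative_differences: int = 0

    def save(self, path: str | Path) -> None:
        """Persist the model (joblib binary + JSON sidecar)."""
        path = Path(path)
        joblib.dump(self, path)
        sidecar = {
            "background_features": self.background_features,
            "smoke_features": self.smoke_features,
            "n_trees": self.rf_params.n_trees,
            "min_leaf": self.rf_params.min_leaf,
            "max_features": self.rf_params.max_features,
            "smote": {"lo": self.smote_params.lo, "hi": self.smote_params.hi, "k": self.smote_params.k},
            "seed": self.seed,
            "oversampled_fraction": self.oversampled_fraction,
            "importances_background": self.importances_background.to_dict(),
            "importances_total": self.importances_total.to_dict(),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @staticmethod
    def load(path: str | Path) -> "SeparationModel":
        return joblib.load(path)


def _observed(table: pd.DataFrame, target_col: str) -> pd.DataFrame:
    return table[table[target_col].notna()].reset_index(drop=True)


def train(
    smoke_table: pd.DataFrame,
    background_table: pd.DataFrame,
    rf_params: RFParams = RFParams(),
    smote_params: SmoteParams = SmoteParams(),
    seed: int = 0,
    target_col: str = "obs_pm25",
    apply_smote: bool = True,
) -> SeparationModel:
    """Train the background and total regressors on their observed rows.

    SMOTE augmentation is applied to each training table independently
    before fitting; the overall oversampled fraction is logged and stored.
    Raises if either table has no observed rows, naming it.
    """
    smoke_obs = _observed(smoke_table, target_col)
    back_obs = _observed(background_table, target_col)
    if back_obs.empty:
        raise ValueError("no observed rows in the no-smoke training table")
    if smoke_obs.empty:
        raise ValueError("no observed rows in the smoke training table")

    ss = np.random.SeedSequence(seed).spawn(4)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss]

    n_before = len(smoke_obs) + len(back_obs)
    if apply_smote:
        smoke_obs = smote_augment(smoke_obs, SMOKE_FEATURES, target_col, smote_params, seeds[0])
        back_obs = smote_augment(back_obs, BACKGROUND_FEATURES, target_col, smote_params, seeds[1])
    n_after = len(smoke_obs) + len(back_obs)
    oversampled = (n_after - n_before) / n_after if n_after else 0.0
    logger.info("SMOTE oversampled fraction: %.4f", oversampled)

    f_back = rf_params.make(len(BACKGROUND_FEATURES), seeds[2])
    f_back.fit(back_obs[BACKGROUND_FEATURES], back_obs[target_col])
    f_tot = rf_params.make(len(SMOKE_FEATURES), seeds[3])
    f_tot.fit(smoke_obs[SMOKE_FEATURES], smoke_obs[target_col])

    return SeparationModel(
        f_background=f_back,
        f_total=f_tot,
        background_features=list(BACKGROUND_FEATURES),
        smoke_features=list(SMOKE_FEATURES),
        rf_params=rf_params,
        smote_params=smote_params,
        seed=seed,
        importances_background=pd.Series(
            f_back.feature_importances_, index=BACKGROUND_FEATURES
        ).sort_values(ascending=False),
        importances_total=pd.Series(
            f_tot.feature_importances_, index=SMOKE_FEATURES
        ).sort_values(ascending=False),
        oversampled_fraction=oversampled,
    )


def predict_smoke(model: SeparationModel, smoke_rows: pd.DataFrame) -> pd.DataFrame:
    """Attribute smoke PM2.5 on smoke-impacted cell-days by difference.

    The total model predicts on the with-fire CTM features, the background
    model on the no-fire CTM features for the same cell-days;
    ``smoke_pred = max(total_pred - background_pred, 0)`` and the count of
    negative raw differences is logged and stored on the model.
    Returns columns ``cell_id, date, iy, ix, total_pred, background_pred,
    smoke_pred``.
    """
    missing = [
        c
        for c in set(model.smoke_features) | set(model.background_features)
        if c not in smoke_rows.columns
    ]
    if missing:
        raise ValueError(f"smoke rows missing feature column(s): {sorted(missing)}")
    if "smoke" in smoke_rows.columns and not smoke_rows["smoke"].all():
        raise ValueError("predict_smoke expects smoke-labeled rows only")

    total_pred = model.f_total.predict(smoke_rows[model.smoke_features])
    background_pred = model.f_background.predict(smoke_rows[model.background_features])
    diff = total_pred - background_pred
    n_neg = int((diff < 0).sum())
    model.n_negative_differences = n_neg
    logger.info("negative total-minus-background differences floored at 0: %d", n_neg)

    out = smoke_rows[["cell_id", "date", "iy", "ix"]].copy()
    out["total_pred"] = total_pred
    out["background_pred"] = background_pred
    out["smoke_pred"] = np.maximum(diff, 0.0)
    return out
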