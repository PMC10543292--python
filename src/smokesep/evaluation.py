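"""Cross-validated performance of the separation regressors.

Overall (row-wise), spatial (site/cell-wise) and temporal (date-wise)
k-fold cross-validation, pooled R²/RMSE on out-of-fold predictions, and
monthly/annual aggregation of the out-of-fold prediction table. SMOTE
augmentation is applied inside each training fold only, so no synthetic row
ever derives from a held-out parent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .separation import RFParams, SmoteParams, smote_augment

SCHEMES = ("overall", "spatial", "temporal")

__all__ = ["SCHEMES", "CVResult", "make_folds", "cross_validate", "aggregate_cv", "variable_importance"]


@dataclass
class CVResult:
    """Pooled and per-fold metrics plus the out-of-fold prediction table."""

    scheme: str
    k: int
    r2: float
    rmse: float
    per_fold: pd.DataFrame
    predictions: pd.DataFrame  # site, date, obs, pred, fold


def _pooled_metrics(obs: np.ndarray, pred: np.ndarray) -> tuple[float, float]:
    resid = obs - pred
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    rmse = float(np.sqrt(np.mean(resid**2)))
    return r2, rmse


def make_folds(
    rows: pd.DataFrame,
    scheme: str = "overall",
    k: int = 20,
    seed: int = 0,
    site_col: str = "cell_id",
    date_col: str = "date",
) -> np.ndarray:
    """Assign every row to one of ``k`` test folds.

    ``overall`` partitions rows at random; ``spatial`` partitions sites so
    all rows of a site share a fold; ``temporal`` partitions dates likewise.
    Raises when there are fewer groups than folds.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    n = len(rows)
    if scheme == "overall":
        if n < k:
            raise ValueError(f"{n} rows < {k} folds")
        return rng.permutation(np.arange(n) % k)
    col = site_col if scheme == "spatial" else date_col
    groups = np.sort(rows[col].unique())
    if len(groups) < k:
        raise ValueError(f"{len(groups)} distinct {col} values < {k} folds")
    gf = rng.permutation(np.arange(len(groups)) % k)
    mapping = dict(zip(groups, gf))
    return rows[col].map(mapping).to_numpy()


def cross_validate(
    table: pd.DataFrame,
    feature_cols: list[str],
    scheme: str = "overall",
    k: int = 20,
    seed: int = 0,
    rf_params: RFParams = RFParams(),
    smote_params: SmoteParams | None = SmoteParams(),
    target_col: str = "obs_pm25",
    site_col: str = "cell_id",
    date_col: str = "date",
) -> CVResult:
    """k-fold cross-validation of one regressor on its observed rows.

    Every observed row receives exactly one out-of-fold prediction; R² and
    RMSE are computed on the pooled out-of-fold table (``R² = 1 −
    SS_res/SS_tot``). Pass ``smote_params=None`` to disable within-fold
    augmentation.
    """
    rows = table[table[target_col].notna()].reset_index(drop=True)
    if rows.empty:
        raise ValueError("no observed rows to cross-validate")
    folds = make_folds(rows, scheme, k, seed, site_col, date_col)

    ss = np.random.SeedSequence(seed).spawn(2 * k)
    sub_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss]

    pred = np.full(len(rows), np.nan)
    per_fold = []
    for f in range(k):
        test = folds == f
        train_rows = rows[~test]
        if train_rows.empty:
            raise ValueError(f"fold {f} has an empty training set")
        if smote_params is not None:
            train_rows = smote_augment(
                train_rows, feature_cols, target_col, smote_params, sub_seeds[2 * f]
            )
        model = rf_params.make(len(feature_cols), sub_seeds[2 * f + 1])
        model.fit(train_rows[feature_cols], train_rows[target_col])
        p = model.predict(rows.loc[test, feature_cols])
        pred[test] = p
        r2_f, rmse_f = _pooled_metrics(rows.loc[test, target_col].to_numpy(), p)
        per_fold.append({"fold": f, "n_test": int(test.sum()), "r2": r2_f, "rmse": rmse_f})

    r2, rmse = _pooled_metrics(rows[target_col].to_numpy(), pred)
    predictions = pd.DataFrame(
        {
            "site": rows[site_col],
            "date": rows[date_col],
            "obs": rows[target_col],
            "pred": pred,
            "fold": folds,
        }
    )
    return CVResult(
        scheme=scheme, k=k, r2=r2, rmse=rmse, per_fold=pd.DataFrame(per_fold), predictions=predictions
    )


def aggregate_cv(
    predictions: pd.DataFrame,
    level: str = "monthly",
    days_per_month: int = 30,
    days_per_year: int = 120,
    min_days: int = 1,
) -> tuple[float, pd.DataFrame]:
    """R² of site-period means of the out-of-fold predictions.

    ``monthly`` periods are consecutive ``days_per_month``-day blocks,
    ``annual`` periods are study years; site-periods with fewer than
    ``min_days`` observed days are dropped. Returns ``(r2, site_period_table)``.
    """
    if level not in ("monthly", "annual"):
        raise ValueError("level must be 'monthly' or 'annual'")
    span = days_per_month if level == "monthly" else days_per_year
    df = predictions.copy()
    df["period"] = df["date"] // span
    g = df.groupby(["site", "period"]).agg(
        obs=("obs", "mean"), pred=("pred", "mean"), n_days=("obs", "count")
    )
    g = g[g["n_days"] >= min_days].reset_index()
    r2, _ = _pooled_metrics(g["obs"].to_numpy(), g["pred"].to_numpy())
    return r2, g


def variable_importance(model) -> pd.Series:
    """Impurity-based importances of a fitted forest, normalized, descending."""
    if not hasattr(model, "feature_importances_"):
        raise ValueError("model is not a fitted forest")
    try:
        imp = pd.Series(model.feature_importances_, index=model.feature_names_in_)
    except AttributeError:
        imp = pd.Series(model.feature_importances_)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return imp.sort_values(ascending=False)
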