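"""Random-forest downscaling of provincial emission intensity to counties.

A forest is trained on pooled (province, year) rows — emission intensity
(ton CO2-eq/km2) against the selected per-area covariates — evaluated with a
90/10 hold-out plus 10-fold cross-validation, then applied to county-level
covariates.  Raw county predictions are finally rescaled per (province,
year) so that county emissions (intensity x area) sum exactly to the
provincial inventory total: a multiplicative mass-balance constraint that
preserves within-province ranking and cannot create negative intensities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import KFold, LeaveOneOut

__all__ = [
    "DownscaleError",
    "DownscalingModel",
    "split_data",
    "fit",
    "evaluate",
    "r2_rmse",
    "predict_counties",
    "adjust_to_provincial",
]

logger = logging.getLogger(__name__)


class DownscaleError(ValueError):
    """Raised on schema mismatches, invalid inputs, or impossible scaling."""


@dataclass
class DownscalingModel:
    """Fitted downscaling regressor with its covariate schema and diagnostics.

    ``covariates`` is the ordered schema shared between fit and predict;
    ``diagnostics`` holds R2/RMSE for the training rows and the mean over CV
    folds (and the hold-out test set when evaluated).
    """

    regressor: RandomForestRegressor
    covariates: tuple[str, ...]
    target: str
    seed: int
    n_trees: int
    diagnostics: dict = field(default_factory=dict)

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.covariates if c not in rows.columns]
        if missing:
            raise DownscaleError(f"rows missing model covariates: {missing}")
        X = rows[list(self.covariates)].to_numpy(dtype=float)
        if np.isnan(X).any():
            raise DownscaleError("NaN in covariates at predict time")
        return self.regressor.predict(X)


def split_data(
    rows: pd.DataFrame, test_frac: float = 0.10, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Randomly partition rows into train/test sets, |test| = round(f * n).

    The partition is disjoint and exhaustive and reproducible per seed.
    """
    if not 0 < test_frac < 1:
        raise DownscaleError(f"test_frac must be in (0, 1), got {test_frac!r}")
    n = len(rows)
    if n < 10:
        raise DownscaleError(f"need at least 10 rows to split, got {n}")
    n_test = int(round(test_frac * n))
    if n_test == 0:
        raise DownscaleError(
            f"test_frac {test_frac} with {n} rows yields an empty test set"
        )
    perm = np.random.default_rng(seed).permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return rows.iloc[train_idx].copy(), rows.iloc[test_idx].copy()


def r2_rmse(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    """R2 (1 - SS_res/SS_tot) and RMSE of predictions against targets.

    A zero-variance target makes R2 undefined; it is returned as NaN with
    the RMSE still computed.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    rmse = float(np.sqrt(mean_squared_error(y_true, y_pred)))
    if np.ptp(y_true) == 0:
        return float("nan"), rmse
    return float(r2_score(y_true, y_pred)), rmse


def fit(
    train: pd.DataFrame,
    covariates: list[str],
    target: str = "target",
    n_trees: int = 500,
    seed: int = 0,
    max_features: float = 1 / 3,
    cv: str = "kfold",
    cv_folds: int = 10,
) -> DownscalingModel:
    """Fit the downscaling forest and populate its diagnostics.

    Parameters
    ----------
    train
        Provincial rows: one row per (province, year) with the target
        intensity column and the selected per-area covariate columns.
    covariates
        Ordered covariate schema (the indicators chosen by screening).
    cv
        ``"kfold"`` (default) records mean R2/RMSE over ``cv_folds``
        shuffled folds; ``"loo"`` records leave-one-out diagnostics with R2
        computed on the pooled held-out predictions.
    """
    if train.empty:
        raise DownscaleError("training set is empty")
    missing = [c for c in [*covariates, target] if c not in train.columns]
    if missing:
        raise DownscaleError(f"training rows missing columns: {missing}")
    X = train[list(covariates)].to_numpy(dtype=float)
    y = train[target].to_numpy(dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        bad_rows = train.index[
            np.isnan(X).any(axis=1) | np.isnan(y)
        ].tolist()
        raise DownscaleError(f"NaN in covariates/target at rows: {bad_rows[:10]}")

    forest = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=max_features,
        random_state=seed,
        n_jobs=1,
    ).fit(X, y)

    train_r2, train_rmse = r2_rmse(y, forest.predict(X))
    diagnostics = {"train_r2": train_r2, "train_rmse": train_rmse}

    if cv == "kfold":
        folds = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        r2s, rmses = [], []
        for tr, te in folds.split(X):
            cv_forest = RandomForestRegressor(
                n_estimators=n_trees,
                max_features=max_features,
                random_state=seed,
                n_jobs=1,
            ).fit(X[tr], y[tr])
            r2, rmse = r2_rmse(y[te], cv_forest.predict(X[te]))
            r2s.append(r2)
            rmses.append(rmse)
        finite = [v for v in r2s if not np.isnan(v)]
        diagnostics.update(
            cv_r2_mean=float(np.mean(finite)) if finite else float("nan"),
            cv_rmse_mean=float(np.mean(rmses)),
            cv_folds=cv_folds,
        )
    elif cv == "loo":
        preds = np.empty_like(y)
        for tr, te in LeaveOneOut().split(X):
            loo_forest = RandomForestRegressor(
                n_estimators=n_trees,
                max_features=max_features,
                random_state=seed,
                n_jobs=1,
            ).fit(X[tr], y[tr])
            preds[te] = loo_forest.predict(X[te])
        loo_r2, loo_rmse = r2_rmse(y, preds)
        diagnostics.update(cv_r2_mean=loo_r2, cv_rmse_mean=loo_rmse, cv_folds=len(y))
    else:
        raise DownscaleError(f"unknown cv mode: {cv!r}")

    return DownscalingModel(
        regressor=forest,
        covariates=tuple(covariates),
        target=target,
        seed=seed,
        n_trees=n_trees,
        diagnostics=diagnostics,
    )


def evaluate(
    model: DownscalingModel, rows: pd.DataFrame, label: str | None = None
) -> tuple[float, float]:
    """R2 and RMSE of the model on held-out rows (pure function of both).

    With ``label`` given, the metrics are also recorded in the model's
    diagnostics under ``{label}_r2`` / ``{label}_rmse``.
    """
    if rows.empty:
        raise DownscaleError("evaluation rows are empty")
    r2, rmse = r2_rmse(rows[model.target].to_numpy(dtype=float), model.predict(rows))
    if label is not None:
        model.diagnostics[f"{label}_r2"] = r2
        model.diagnostics[f"{label}_rmse"] = rmse
    return r2, rmse


def predict_counties(model: DownscalingModel, counties: pd.DataFrame) -> pd.DataFrame:
    """Predict raw county emission intensity from county covariates.

    ``counties`` needs columns ``county_id, province_id, year, area_km2``
    plus the model's covariate schema; returns those keys with a
    ``raw_intensity`` column (ton CO2-eq/km2).  Forest predictions are convex
    combinations of training targets, so non-negative targets give
    non-negative intensities.
    """
    required = {"county_id", "province_id", "year", "area_km2"}
    missing = required - set(counties.columns)
    if missing:
        raise DownscaleError(f"county table missing columns: {sorted(missing)}")
    if counties["province_id"].isna().any():
        bad = counties.loc[counties["province_id"].isna(), "county_id"].unique()
        raise DownscaleError(f"counties missing province mapping: {sorted(bad)[:10]}")
    if counties.duplicated(["county_id", "year"]).any():
        raise DownscaleError("duplicate (county_id, year) rows")
    if (counties["area_km2"] <= 0).any():
        raise DownscaleError("county areas must be positive")

    out = counties[["county_id", "province_id", "year", "area_km2"]].copy()
    out["raw_intensity"] = model.predict(counties)

    zero_cov = (counties[list(model.covariates)].to_numpy(dtype=float) == 0).all(axis=1)
    flagged = zero_cov & (out["raw_intensity"].to_numpy() > 0)
    if flagged.any():
        logger.warning(
            "%d county rows with all-zero covariates but positive predicted "
            "intensity (no zero-cropland special-casing is applied)",
            int(flagged.sum()),
        )
    return out


def adjust_to_provincial(
    estimates: pd.DataFrame, provincial: pd.DataFrame
) -> pd.DataFrame:
    """Scale raw county intensities to conserve provincial emission totals.

    For each (province, year) the scaling factor is the provincial inventory
    total divided by the sum of raw county emissions
    (``raw_intensity * area_km2``); adjusted intensity is raw x factor, so
    county emissions sum exactly to the provincial total.  A zero provincial
    target sets all adjusted intensities (and the factor) to zero; a zero raw
    sum against a non-zero target is an error — there is nothing to scale.
    """
    required = {"county_id", "province_id", "year", "area_km2", "raw_intensity"}
    missing = required - set(estimates.columns)
    if missing:
        raise DownscaleError(f"estimates missing columns: {sorted(missing)}")
    prov = provincial.rename(columns={"region_id": "province_id"})
    if "total_co2e_t" not in prov.columns:
        raise DownscaleError("provincial records need a total_co2e_t column")

    est = estimates.copy()
    est["_raw_emis"] = est["raw_intensity"] * est["area_km2"]
    sums = (
        est.groupby(["province_id", "year"], as_index=False)["_raw_emis"]
        .sum()
        .merge(prov[["province_id", "year", "total_co2e_t"]],
               on=["province_id", "year"], how="left")
    )
    no_target = sums["total_co2e_t"].isna()
    if no_target.any():
        keys = sums.loc[no_target, ["province_id", "year"]].to_records(index=False)
        raise DownscaleError(
            f"no provincial total for province-years: {list(keys)[:10]}"
        )
    unscalable = (sums["_raw_emis"] == 0) & (sums["total_co2e_t"] != 0)
    if unscalable.any():
        keys = sums.loc[unscalable, ["province_id", "year"]].to_records(index=False)
        raise DownscaleError(
            f"zero raw emission sum with non-zero provincial target: {list(keys)[:10]}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        sums["scaling_factor"] = np.where(
            sums["total_co2e_t"] == 0.0,
            0.0,
            sums["total_co2e_t"] / sums["_raw_emis"],
        )

    out = est.merge(
        sums[["province_id", "year", "scaling_factor"]],
        on=["province_id", "year"],
        how="left",
    )
    out["adjusted_intensity"] = out["raw_intensity"] * out["scaling_factor"]
    return out.drop(columns="_raw_emis")
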