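"""Diagnostics against independent reference intensity products.

Covers the three checks used to assess a downscaled county product: zonal
extraction of a gridded reference to county means via an explicit
cell-to-county area-weight lookup, Pearson correlation / linear-fit R2
between two county series, and the national emission trend series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ValidationError",
    "ComparisonResult",
    "zonal_extract",
    "compare",
    "national_series",
]

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Raised on invalid grids, weight tables, or degenerate comparisons."""


@dataclass
class ComparisonResult:
    """County-level agreement between two intensity products for one year."""

    year: int | None
    reference: str
    n: int
    pearson_r: float
    r_squared: float
    bias: float  # mean(ours - reference), ton CO2-eq/km2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def zonal_extract(grid: np.ndarray, weights: pd.DataFrame) -> pd.Series:
    """Area-weighted county means of a gridded intensity field.

    Parameters
    ----------
    grid
        2-D array of cell values (e.g. a 10-km reference raster read into
        memory).  NaN cells are treated as no-data and excluded.
    weights
        Cell-to-county lookup with columns ``county_id, row, col, weight``
        (weight = the cell area falling in the county).  This replaces GIS
        polygon intersection with an explicit area-weight contract.

    Returns
    -------
    pandas.Series
        county_id -> weighted mean.  Counties whose cells are all no-data
        are omitted and logged.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2:
        raise ValidationError(f"grid must be 2-D, got shape {grid.shape}")
    required = {"county_id", "row", "col", "weight"}
    if not required <= set(weights.columns):
        raise ValidationError(f"weight table must have columns {sorted(required)}")
    if (weights["weight"] <= 0).any():
        raise ValidationError("weights must be positive")
    rows = weights["row"].to_numpy(dtype=int)
    cols = weights["col"].to_numpy(dtype=int)
    if (rows < 0).any() or (rows >= grid.shape[0]).any() or (cols < 0).any() or (
        cols >= grid.shape[1]
    ).any():
        raise ValidationError("weight table indexes cells outside the grid")

    values = grid[rows, cols]
    ok = ~np.isnan(values)
    df = pd.DataFrame(
        {
            "county_id": weights["county_id"].to_numpy()[ok],
            "wx": values[ok] * weights["weight"].to_numpy()[ok],
            "w": weights["weight"].to_numpy()[ok],
        }
    )
    if df.empty:
        raise ValidationError("no county intersects a valid grid cell")
    agg = df.groupby("county_id").sum()
    means = agg["wx"] / agg["w"]
    dropped = set(weights["county_id"].unique()) - set(means.index)
    if dropped:
        logger.warning("counties with no valid grid coverage omitted: %s",
                       sorted(dropped)[:10])
    return means.rename("mean_intensity")


def compare(
    ours: pd.Series | dict,
    reference: pd.Series | dict,
    year: int | None = None,
    name: str = "reference",
) -> ComparisonResult:
    """Pearson r and linear-fit R2 between two county-indexed series.

    Computed over the intersection of county keys (at least 3 required);
    R2 is that of the simple linear regression of the reference on our
    values, which for a single predictor equals r^2 in either direction.
    """
    a = pd.Series(ours, dtype=float)
    b = pd.Series(reference, dtype=float)
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValidationError(
            f"need at least 3 shared counties, got {len(shared)}"
        )
    x = a.loc[shared].to_numpy()
    y = b.loc[shared].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance in one of the compared series")
    r = float(stats.pearsonr(x, y).statistic)
    fit = stats.linregress(x, y)
    return ComparisonResult(
        year=year,
        reference=name,
        n=int(len(shared)),
        pearson_r=r,
        r_squared=float(fit.rvalue**2),
        bias=float(np.mean(x - y)),
    )


def national_series(records: pd.DataFrame) -> pd.DataFrame:
    """National totals and mean intensity per year from regional records.

    ``records`` is the intensity table produced by the inventory
    (``region_id, year, total_co2e_t, area_km2``).  National intensity is
    the area-weighted mean: total emissions over total land area.
    """
    required = {"region_id", "year", "total_co2e_t", "area_km2"}
    missing = required - set(records.columns)
    if missing:
        raise ValidationError(f"records missing columns: {sorted(missing)}")
    out = (
        records.groupby("year", as_index=False)
        .agg(total_co2e_t=("total_co2e_t", "sum"), area_km2=("area_km2", "sum"))
        .sort_values("year", ignore_index=True)
    )
    out["mean_intensity"] = out["total_co2e_t"] / out["area_km2"]
    return out
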