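"""Activity-based CO2-equivalent inventory for crop farming.

Provincial (or any region's) emissions are accounted from six agricultural
activities — crop residue open burning, rice cultivation, cropland emissions
(in-field CH4/N2O), machinery use, nitrogen fertilizer production, and
pesticide production.  Each activity amount is multiplied by per-gas emission
factors and converted to CO2-equivalents with 100-yr global warming
potentials; totals are normalised by region land area to an emission
*intensity* in ton CO2-eq/km2.

Emission-factor values are configuration: the module ships a unit-consistent
placeholder table (see :mod:`cropcarbon.config`) that users replace with the
factors of their chosen accounting scheme.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "ACTIVITIES",
    "GASES",
    "DEFAULT_GWP",
    "InventoryError",
    "compute_emissions",
    "aggregate_totals",
    "to_intensity",
]

logger = logging.getLogger(__name__)

#: The six crop-farming activity categories covered by the accounting scheme.
ACTIVITIES = (
    "residue_open_burning",
    "rice_cultivation",
    "cropland_emissions",
    "machinery_use",
    "n_fertilizer_production",
    "pesticide_production",
)

GASES = ("CO2", "CH4", "N2O")

#: 100-yr global warming potentials (AR4 convention); overridable everywhere.
DEFAULT_GWP = {"CO2": 1.0, "CH4": 25.0, "N2O": 298.0}


class InventoryError(ValueError):
    """Raised when an activity panel, factor table, or area table is invalid."""


def _validate_gwp(gwp: dict) -> dict:
    gwp = dict(gwp)
    if gwp.get("CO2") != 1.0:
        raise InventoryError(f"GWP of CO2 must be 1, got {gwp.get('CO2')!r}")
    for gas, value in gwp.items():
        if not value > 0:
            raise InventoryError(f"GWP of {gas} must be positive, got {value!r}")
    return gwp


def _validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    required = {"region_id", "year", "activity", "amount"}
    missing = required - set(panel.columns)
    if missing:
        raise InventoryError(f"activity panel missing columns: {sorted(missing)}")
    if (panel["amount"] < 0).any():
        bad = panel.loc[panel["amount"] < 0].iloc[0]
        raise InventoryError(
            "negative activity amount for "
            f"({bad['region_id']}, {bad['year']}, {bad['activity']}): {bad['amount']}"
        )
    dup = panel.duplicated(["region_id", "year", "activity"])
    if dup.any():
        keys = panel.loc[dup, ["region_id", "year", "activity"]].iloc[0].tolist()
        raise InventoryError(f"duplicate activity panel key: {keys}")
    return panel


def _validate_efs(efs: pd.DataFrame) -> pd.DataFrame:
    required = {"activity", "gas", "ef"}
    missing = required - set(efs.columns)
    if missing:
        raise InventoryError(f"emission factor table missing columns: {sorted(missing)}")
    if (efs["ef"] < 0).any():
        raise InventoryError("emission factors must be non-negative")
    if efs.duplicated(["activity", "gas"]).any():
        raise InventoryError("duplicate (activity, gas) emission factor rows")
    return efs


def compute_emissions(
    panel: pd.DataFrame,
    efs: pd.DataFrame,
    gwp: dict | None = None,
) -> pd.DataFrame:
    """Convert activity amounts to CO2-eq emissions per region, year, activity.

    Parameters
    ----------
    panel
        Long table with columns ``region_id, year, activity, amount``.
        Amounts are in the physical unit declared by the matching factor row.
    efs
        Emission factor table with columns ``activity, gas, ef`` (and
        optionally ``unit``); one row per gas each activity emits.
    gwp
        Gas -> 100-yr global warming potential.  Defaults to
        :data:`DEFAULT_GWP`; the values used are logged.

    Returns
    -------
    pandas.DataFrame
        Columns ``region_id, year, activity, co2e_t``:
        ``co2e_t = sum_gas amount * ef(activity, gas) * gwp(gas)``.

    Raises
    ------
    InventoryError
        If an activity present in the panel has no factor row, an amount is
        negative, panel keys duplicate, or a factor-table gas has no GWP.
    """
    gwp = _validate_gwp(DEFAULT_GWP if gwp is None else gwp)
    panel = _validate_panel(panel)
    efs = _validate_efs(efs)
    logger.info("computing CO2-eq emissions with GWP %s", gwp)

    present = set(panel["activity"].unique())
    covered = set(efs["activity"].unique())
    uncovered = present - covered
    if uncovered:
        raise InventoryError(
            f"no emission factor row for activities: {sorted(uncovered)}"
        )
    unknown_gas = set(efs["gas"].unique()) - set(gwp)
    if unknown_gas:
        raise InventoryError(f"no GWP configured for gases: {sorted(unknown_gas)}")

    merged = panel.merge(efs[["activity", "gas", "ef"]], on="activity", how="left")
    merged["co2e_t"] = (
        merged["amount"].to_numpy()
        * merged["ef"].to_numpy()
        * merged["gas"].map(gwp).to_numpy()
    )
    out = (
        merged.groupby(["region_id", "year", "activity"], as_index=False, sort=True)[
            "co2e_t"
        ]
        .sum()
    )
    return out


def aggregate_totals(emissions: pd.DataFrame) -> pd.DataFrame:
    """Sum per-activity CO2-eq emissions to region-year totals.

    Accepts the output of :func:`compute_emissions`; returns columns
    ``region_id, year, total_co2e_t``.
    """
    return (
        emissions.groupby(["region_id", "year"], as_index=False, sort=True)["co2e_t"]
        .sum()
        .rename(columns={"co2e_t": "total_co2e_t"})
    )


def to_intensity(records: pd.DataFrame, areas: pd.DataFrame) -> pd.DataFrame:
    """Normalise total emissions by land area to ton CO2-eq/km2.

    Parameters
    ----------
    records
        Either per-activity emissions (columns include ``activity, co2e_t``)
        or region-year totals (column ``total_co2e_t``).
    areas
        Table with columns ``region_id, area_km2``; one positive area per
        region appearing in ``records``.

    Returns
    -------
    pandas.DataFrame
        Columns ``region_id, year, total_co2e_t, area_km2,
        intensity_t_per_km2``.
    """
    if "total_co2e_t" not in records.columns:
        records = aggregate_totals(records)
    required = {"region_id", "area_km2"}
    if not required <= set(areas.columns):
        raise InventoryError(f"area table must have columns {sorted(required)}")
    if areas.duplicated("region_id").any():
        raise InventoryError("duplicate region_id rows in area table")

    out = records.merge(areas[["region_id", "area_km2"]], on="region_id", how="left")
    missing = out.loc[out["area_km2"].isna(), "region_id"].unique()
    if len(missing):
        raise InventoryError(f"missing land area for regions: {sorted(missing)}")
    if (out["area_km2"] <= 0).any():
        bad = out.loc[out["area_km2"] <= 0, "region_id"].unique()
        raise InventoryError(f"non-positive land area for regions: {sorted(bad)}")
    out["intensity_t_per_km2"] = out["total_co2e_t"] / out["area_km2"]
    return out
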