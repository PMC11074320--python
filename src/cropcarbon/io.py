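"""CSV readers/writers for the pipeline's tabular interchange formats.

All stage inputs and outputs are plain CSV with a header row so any stage
can be re-run in isolation and audited with ordinary tools.  The county
result can additionally be written as a wide county x year sheet mirroring
the layout of published county intensity datasets (CSV, or a single-sheet
spreadsheet when openpyxl is available).
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

__all__ = [
    "read_activity_panel",
    "read_areas",
    "read_indicator_matrix",
    "read_county_covariates",
    "read_reference_table",
    "write_emission_records",
    "write_importance_report",
    "write_county_estimates",
    "write_county_matrix",
    "file_digest",
]


def _read_csv(path: str | Path, required: set[str], what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{what} file not found: {path}")
    df = pd.read_csv(path)
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{what} file {path} missing columns: {sorted(missing)}")
    return df


def read_activity_panel(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, {"region_id", "year", "activity", "amount"},
                     "activity panel")


def read_areas(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, {"region_id", "area_km2"}, "area table")


def read_indicator_matrix(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, {"region_id", "year", "target"}, "indicator matrix")


def read_county_covariates(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, {"county_id", "province_id", "year", "area_km2"},
                     "county covariates")


def read_reference_table(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, {"county_id"}, "reference table")


def write_emission_records(
    emissions: pd.DataFrame, intensity: pd.DataFrame, path: str | Path
) -> Path:
    """Write long-format emission records: activity rows plus a total row.

    ``emissions`` is the per-activity table from the inventory;
    ``intensity`` the region-year totals with intensity.  Each region-year
    gets one row per activity and a ``total`` row carrying the intensity.
    """
    path = Path(path)
    act = emissions.rename(columns={"co2e_t": "value"}).copy()
    tot = intensity.rename(columns={"total_co2e_t": "value"}).copy()
    tot["activity"] = "total"
    cols = ["region_id", "year", "activity", "value", "area_km2",
            "intensity_t_per_km2"]
    out = pd.concat([act, tot], ignore_index=True).reindex(columns=cols)
    out = out.sort_values(["region_id", "year", "activity"], ignore_index=True)
    out.to_csv(path, index=False)
    return path


def write_importance_report(report, path: str | Path) -> Path:
    path = Path(path)
    report.to_frame().to_csv(path, index=False)
    return path


def write_county_estimates(estimates: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    estimates.to_csv(path, index=False)
    return path


def write_county_matrix(
    estimates: pd.DataFrame,
    path: str | Path,
    value: str = "adjusted_intensity",
) -> Path:
    """Write county rows x year columns of intensity (wide layout).

    ``path`` ending in ``.xlsx`` writes a single-sheet spreadsheet;
    anything else writes CSV.
    """
    path = Path(path)
    wide = (
        estimates.pivot(index=["county_id", "province_id"], columns="year",
                        values=value)
        .sort_index()
        .reset_index()
    )
    wide.columns = [str(c) for c in wide.columns]
    if path.suffix == ".xlsx":
        wide.to_excel(path, index=False, sheet_name="county_intensity")
    else:
        wide.to_csv(path, index=False)
    return path


def file_digest(path: str | Path) -> str:
    """SHA-256 digest of a file, for run manifests."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
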