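"""End-to-end orchestration: inventory -> screen -> downscale -> adjust.

Chains the stages on in-memory tables; the CLI wraps this with file I/O.
Useful both for synthetic-world experiments (where ground truth is known)
and for real provincial statistics plus county covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import downscale, inventory, screen

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything the chained stages produce."""

    emissions: pd.DataFrame               # per-activity CO2-eq
    provincial_intensity: pd.DataFrame    # region-year totals + intensity
    report: "screen.ImportanceReport"
    model: "downscale.DownscalingModel"
    estimates: pd.DataFrame               # county raw + adjusted intensity
    meta: dict = field(default_factory=dict)


def run_pipeline(
    activity_panel: pd.DataFrame,
    province_areas: pd.DataFrame,
    indicator_matrix: pd.DataFrame,
    county_covariates: pd.DataFrame,
    emission_factors: pd.DataFrame,
    gwp: dict | None = None,
    seed: int = 0,
    cum_threshold: float = 0.95,
    screen_trees: int = 500,
    downscale_trees: int = 500,
    test_frac: float = 0.10,
    cv_folds: int = 10,
) -> PipelineResult:
    """Run the full provincial-to-county downscaling pipeline.

    Steps: (1) activity-based CO2-eq inventory and provincial intensity;
    (2) random-forest indicator screening with cumulative-importance
    selection; (3) 90/10 split, forest fit with 10-fold CV, hold-out
    evaluation; (4) county prediction and multiplicative mass-balance
    adjustment to the provincial totals.

    The ``target`` column of ``indicator_matrix`` is ignored if present and
    recomputed from the inventory so the screening target and the constraint
    totals are always consistent.
    """
    emissions = inventory.compute_emissions(activity_panel, emission_factors, gwp)
    provincial = inventory.to_intensity(emissions, province_areas)

    matrix = indicator_matrix.drop(columns=["target"], errors="ignore").merge(
        provincial[["region_id", "year", "intensity_t_per_km2"]],
        on=["region_id", "year"],
        how="inner",
    ).rename(columns={"intensity_t_per_km2": "target"})
    if matrix.empty:
        raise ValueError("no overlap between indicator matrix and inventory rows")

    report = screen.select_indicators(
        screen.rank_indicators(matrix, seed=seed, n_trees=screen_trees),
        cum_threshold=cum_threshold,
    )
    selected = [c for c in report.selected if c in county_covariates.columns]
    if not selected:
        raise ValueError(
            "none of the selected indicators has a county-level covariate: "
            f"{report.selected}"
        )

    train, test = downscale.split_data(matrix, test_frac=test_frac, seed=seed)
    model = downscale.fit(
        train, selected, target="target", n_trees=downscale_trees, seed=seed,
        cv_folds=cv_folds,
    )
    downscale.evaluate(model, test, label="test")

    raw = downscale.predict_counties(model, county_covariates)
    estimates = downscale.adjust_to_provincial(
        raw, provincial[["region_id", "year", "total_co2e_t"]]
    )
    return PipelineResult(
        emissions=emissions,
        provincial_intensity=provincial,
        report=report,
        model=model,
        estimates=estimates,
        meta={
            "seed": seed,
            "selected": report.selected,
            "used_covariates": selected,
            "diagnostics": dict(model.diagnostics),
        },
    )
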