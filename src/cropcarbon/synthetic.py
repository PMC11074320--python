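"""Seeded synthetic worlds with a known province-county generative link.

The generator emulates the three inputs the pipeline consumes — a provincial
statistics panel (activity amounts and 12 candidate indicators), county
per-area covariates, and a noisy reference intensity product — built so that
ground truth is known at every stage:

* county covariates are log-normal fields with province random effects;
* true county intensity is a monotone linear function of the 4 informative
  covariates times multiplicative log-normal noise (intensities are strictly
  positive); the 8 nuisance indicators are generated independently of it;
* provincial indicators are exact area-weighted county means, and activity
  amounts are back-derived so the inventory totals equal the sum of true
  county emissions exactly;
* the reference product is truth plus independent noise.

Regeneration with the same seed is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .inventory import DEFAULT_GWP

__all__ = [
    "INFORMATIVE_INDICATORS",
    "NUISANCE_INDICATORS",
    "SYNTHETIC_EMISSION_FACTORS",
    "SyntheticConfig",
    "SyntheticWorld",
    "generate",
]

#: The 4 indicators that truly drive intensity in the synthetic world,
#: mirroring the screening outcome on real provincial statistics.
INFORMATIVE_INDICATORS = (
    "total_population",
    "sown_area_of_rice",
    "n_fertilizer_effective_component",
    "grain_crop_output",
)

#: The 8 candidate indicators generated independently of intensity.
NUISANCE_INDICATORS = (
    "agricultural_pesticide_use",
    "large_animals",
    "sheep_and_goats",
    "agricultural_machinery_power",
    "large_medium_tractors",
    "small_tractors",
    "gross_output_agri_forestry_husbandry_fishery",
    "gross_output_agriculture",
)

#: Monotone linear link: intensity = intercept + sum coef_j * x_j, all
#: coefficients positive so the link is monotone in every covariate.
_LINK_INTERCEPT = 5.0
_LINK_COEF = {
    "total_population": 40.0,
    "sown_area_of_rice": 35.0,
    "n_fertilizer_effective_component": 30.0,
    "grain_crop_output": 25.0,
}

#: Activity shares of each province-year total used when back-deriving
#: activity amounts (sum to 1).
_ACTIVITY_SHARES = {
    "residue_open_burning": 0.10,
    "rice_cultivation": 0.35,
    "cropland_emissions": 0.20,
    "machinery_use": 0.10,
    "n_fertilizer_production": 0.18,
    "pesticide_production": 0.07,
}

#: Synthetic emission-factor table (one gas per activity, unit-consistent);
#: a stand-in for a real accounting scheme's factors, used only so the
#: inventory arithmetic can be exercised with known totals.
SYNTHETIC_EMISSION_FACTORS = pd.DataFrame(
    [
        ("residue_open_burning", "CH4", 0.0045, "t residue"),
        ("rice_cultivation", "CH4", 13.0, "km2 rice"),
        ("cropland_emissions", "N2O", 0.02, "km2 cropland"),
        ("machinery_use", "CO2", 0.59, "t diesel-eq"),
        ("n_fertilizer_production", "CO2", 1.74, "t N"),
        ("pesticide_production", "CO2", 4.93, "t pesticide"),
    ],
    columns=["activity", "gas", "ef", "unit"],
)


class SyntheticError(ValueError):
    """Raised on invalid generator configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of a synthetic world.

    Defaults: 15 provinces x 20 counties x 10 years with multiplicative
    log-normal noise at coefficient of variation 0.05 on true intensity, and
    an independent CV 0.10 on the reference product.
    """

    seed: int = 0
    n_provinces: int = 15
    counties_per_province: int = 20
    year_start: int = 2000
    year_end: int = 2009
    noise_cv: float = 0.05
    reference_noise_cv: float = 0.10
    #: log-sd of the province, province-year and county-year covariate effects
    sigma_province: float = 0.3
    sigma_year: float = 0.4
    sigma_county: float = 0.15

    def __post_init__(self) -> None:
        if self.n_provinces < 2:
            raise SyntheticError("need at least 2 provinces")
        if self.counties_per_province < 2:
            raise SyntheticError("need at least 2 counties per province")
        if self.year_end - self.year_start + 1 < 2:
            raise SyntheticError("need at least 2 years")
        if self.noise_cv < 0 or self.reference_noise_cv < 0:
            raise SyntheticError("noise CVs must be non-negative")

    @property
    def years(self) -> list[int]:
        return list(range(self.year_start, self.year_end + 1))


@dataclass
class SyntheticWorld:
    """All generated tables plus the parameter manifest."""

    config: SyntheticConfig
    activity_panel: pd.DataFrame          # province x year x activity amounts
    province_areas: pd.DataFrame          # region_id, area_km2
    emission_factors: pd.DataFrame
    gwp: dict
    indicator_matrix: pd.DataFrame        # provincial rows with target
    county_covariates: pd.DataFrame       # county x year covariates + area
    true_county_intensity: pd.DataFrame   # county x year ground truth
    reference: pd.DataFrame               # truth + independent noise
    manifest: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write every table as CSV plus a JSON manifest; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        tables = {
            "activity_panel": self.activity_panel,
            "province_areas": self.province_areas,
            "emission_factors": self.emission_factors,
            "indicator_matrix": self.indicator_matrix,
            "county_covariates": self.county_covariates,
            "true_county_intensity": self.true_county_intensity,
            "reference": self.reference,
        }
        for name, frame in tables.items():
            paths[name] = outdir / f"{name}.csv"
            frame.to_csv(paths[name], index=False)
        paths["gwp"] = outdir / "gwp.json"
        paths["gwp"].write_text(json.dumps(self.gwp, indent=2))
        paths["manifest"] = outdir / "manifest.json"
        paths["manifest"].write_text(json.dumps(self.manifest, indent=2, sort_keys=True))
        return paths


def _lognormal_unit_mean(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative log-normal noise with mean 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def generate(config: SyntheticConfig | None = None, **overrides) -> SyntheticWorld:
    """Generate a seeded synthetic world satisfying every stage's contract.

    Keyword overrides are applied on top of ``config`` (or the defaults),
    e.g. ``generate(seed=7, n_provinces=4)``.
    """
    if config is None:
        config = SyntheticConfig(**overrides)
    elif overrides:
        config = dataclasses.replace(config, **overrides)
    rng = np.random.default_rng(config.seed)

    years = config.years
    provinces = [f"P{i:02d}" for i in range(config.n_provinces)]
    indicators = list(INFORMATIVE_INDICATORS) + list(NUISANCE_INDICATORS)
    n_p, n_c, n_y = config.n_provinces, config.counties_per_province, len(years)
    n_k = len(indicators)

    county_area = rng.lognormal(mean=np.log(2000.0), sigma=0.4, size=(n_p, n_c))
    prov_area = county_area.sum(axis=1)

    # covariate fields: province effect x province-year effect x county-year
    # idiosyncratic term, all log-normal (shape: province, county, year, indicator)
    prov_eff = rng.lognormal(0.0, config.sigma_province, size=(n_p, 1, 1, n_k))
    year_eff = rng.lognormal(0.0, config.sigma_year, size=(n_p, 1, n_y, n_k))
    county_eff = rng.lognormal(0.0, config.sigma_county, size=(n_p, n_c, n_y, n_k))
    x = prov_eff * year_eff * county_eff

    coef = np.array([_LINK_COEF.get(k, 0.0) for k in indicators])
    g = _LINK_INTERCEPT + np.tensordot(x, coef, axes=([3], [0]))  # (p, c, y)
    noise = _lognormal_unit_mean(rng, config.noise_cv, g.shape)
    intensity = g * noise                                          # ground truth
    emissions = intensity * county_area[:, :, None]                # t CO2-eq
    prov_total = emissions.sum(axis=1)                             # (p, y)

    county_ids = np.array(
        [[f"{p}C{c:03d}" for c in range(n_c)] for p in provinces]
    )

    p_idx, c_idx, y_idx = np.meshgrid(
        np.arange(n_p), np.arange(n_c), np.arange(n_y), indexing="ij"
    )
    county_covariates = pd.DataFrame(
        {
            "county_id": county_ids[p_idx.ravel(), c_idx.ravel()],
            "province_id": np.array(provinces)[p_idx.ravel()],
            "year": np.array(years)[y_idx.ravel()],
            "area_km2": county_area[p_idx.ravel(), c_idx.ravel()],
        }
    )
    for j, name in enumerate(indicators):
        county_covariates[name] = x[..., j].ravel()

    true_county_intensity = county_covariates[
        ["county_id", "province_id", "year", "area_km2"]
    ].copy()
    true_county_intensity["intensity_t_per_km2"] = intensity.ravel()

    reference = true_county_intensity[["county_id", "year"]].copy()
    reference["intensity_t_per_km2"] = intensity.ravel() * _lognormal_unit_mean(
        rng, config.reference_noise_cv, intensity.size
    )

    # provincial indicators: exact area-weighted county means; target: exact
    # provincial intensity (total emissions over provincial land area)
    w = county_area / prov_area[:, None]                           # (p, c)
    xbar = np.einsum("pc,pcyk->pyk", w, x)
    prov_intensity = prov_total / prov_area[:, None]
    pp, yy = np.meshgrid(np.arange(n_p), np.arange(n_y), indexing="ij")
    indicator_matrix = pd.DataFrame(
        {
            "region_id": np.array(provinces)[pp.ravel()],
            "year": np.array(years)[yy.ravel()],
            "target": prov_intensity.ravel(),
        }
    )
    for j, name in enumerate(indicators):
        indicator_matrix[name] = xbar[..., j].ravel()

    # back-derive activity amounts so the inventory reproduces prov_total
    # exactly: amount = share * total / (ef * gwp)
    efs = SYNTHETIC_EMISSION_FACTORS
    gwp = dict(DEFAULT_GWP)
    rows = []
    for _, ef_row in efs.iterrows():
        per_unit = ef_row["ef"] * gwp[ef_row["gas"]]
        share = _ACTIVITY_SHARES[ef_row["activity"]]
        amount = share * prov_total / per_unit                     # (p, y)
        rows.append(
            pd.DataFrame(
                {
                    "region_id": np.array(provinces)[pp.ravel()],
                    "year": np.array(years)[yy.ravel()],
                    "activity": ef_row["activity"],
                    "amount": amount.ravel(),
                }
            )
        )
    activity_panel = (
        pd.concat(rows, ignore_index=True)
        .sort_values(["region_id", "year", "activity"], ignore_index=True)
    )

    province_areas = pd.DataFrame({"region_id": provinces, "area_km2": prov_area})

    manifest = {
        "config": dataclasses.asdict(config),
        "informative_indicators": list(INFORMATIVE_INDICATORS),
        "nuisance_indicators": list(NUISANCE_INDICATORS),
        "link": {"intercept": _LINK_INTERCEPT, "coefficients": _LINK_COEF},
        "activity_shares": _ACTIVITY_SHARES,
        "gwp": gwp,
        "n_rows": {
            "provincial": int(n_p * n_y),
            "county": int(n_p * n_c * n_y),
        },
    }
    return SyntheticWorld(
        config=config,
        activity_panel=activity_panel,
        province_areas=province_areas,
        emission_factors=efs.copy(),
        gwp=gwp,
        indicator_matrix=indicator_matrix,
        county_covariates=county_covariates,
        true_county_intensity=true_county_intensity,
        reference=reference,
        manifest=manifest,
    )
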