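"""Default configuration tables and the YAML config loader.

Emission factors are user configuration: the table below is a PLACEHOLDER —
unit-consistent and order-of-magnitude plausible, but not the factors of any
published accounting scheme.  Replace it (via the ``factors`` section of a
config file) with the factors of the scheme you account under.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .inventory import DEFAULT_GWP

__all__ = ["PLACEHOLDER_EMISSION_FACTORS", "DEFAULT_CONFIG", "load_config"]

#: Placeholder per-gas emission factors for the six activities (see module
#: docstring); one row per (activity, gas).
PLACEHOLDER_EMISSION_FACTORS = pd.DataFrame(
    [
        ("residue_open_burning", "CH4", 0.0045, "t residue"),
        ("residue_open_burning", "N2O", 0.00007, "t residue"),
        ("rice_cultivation", "CH4", 13.0, "km2 rice"),
        ("cropland_emissions", "N2O", 0.02, "km2 cropland"),
        ("machinery_use", "CO2", 0.59, "t diesel-eq"),
        ("n_fertilizer_production", "CO2", 1.74, "t N"),
        ("pesticide_production", "CO2", 4.93, "t pesticide"),
    ],
    columns=["activity", "gas", "ef", "unit"],
)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synthetic": {
        "n_provinces": 15,
        "counties_per_province": 20,
        "year_start": 2000,
        "year_end": 2009,
        "noise_cv": 0.05,
        "reference_noise_cv": 0.10,
    },
    "screen": {"cum_threshold": 0.95, "n_trees": 500},
    "downscale": {"n_trees": 500, "test_frac": 0.10, "cv_folds": 10},
    "factors": {
        "gwp": dict(DEFAULT_GWP),
        "emission_factors": PLACEHOLDER_EMISSION_FACTORS.to_dict("records"),
    },
}


def _deep_update(base: dict, extra: dict) -> dict:
    out = dict(base)
    for key, value in extra.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_update(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config, layered over :data:`DEFAULT_CONFIG`."""
    if path is None:
        return _deep_update(DEFAULT_CONFIG, {})
    text = Path(path).read_text()
    user = yaml.safe_load(text) or {}
    if not isinstance(user, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return _deep_update(DEFAULT_CONFIG, user)


def factors_from_config(config: dict) -> tuple[pd.DataFrame, dict]:
    """Extract (emission factor table, GWP dict) from a loaded config."""
    factors = config.get("factors", {})
    efs = pd.DataFrame(factors.get("emission_factors", []))
    gwp = dict(factors.get("gwp", DEFAULT_GWP))
    return efs, gwp
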