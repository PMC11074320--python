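import numpy as np
import pandas as pd
import pytest

from cropcarbon import synthetic


@pytest.fixture(scope="session")
def small_world():
    """A small synthetic world shared by read-only tests."""
    return synthetic.generate(seed=11, n_provinces=4, counties_per_province=5,
                              year_start=2000, year_end=2002)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def simple_panel():
    """One region, one year, one CO2-only activity: amount 100, ef 0.5."""
    panel = pd.DataFrame(
        [{"region_id": "R1", "year": 2000,
          "activity": "machinery_use", "amount": 100.0}]
    )
    efs = pd.DataFrame(
        [{"activity": "machinery_use", "gas": "CO2", "ef": 0.5, "unit": "u"}]
    )
    return panel, efs
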