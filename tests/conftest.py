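import hypothesis
import numpy as np
import pandas as pd
import pytest

hypothesis.settings.register_profile("ci", derandomize=True)
hypothesis.settings.load_profile("ci")

from benthicstatus import default_depletion_table, default_slope
from benthicstatus import synth


@pytest.fixture(scope="session")
def d_table():
    return default_depletion_table()


@pytest.fixture(scope="session")
def slope():
    return default_slope()


@pytest.fixture(scope="session")
def region_spec():
    return synth.SynthRegionSpec(n_cells=900, seed=11)


@pytest.fixture(scope="session")
def effort_grid(region_spec):
    return synth.gen_effort_grid(region_spec)


@pytest.fixture(scope="session")
def sediment_grid(region_spec):
    return synth.gen_sediment_grid(region_spec)


@pytest.fixture(scope="session")
def assessed_cells(effort_grid, sediment_grid, d_table, slope):
    from benthicstatus import assessment

    return assessment.assess_cells(effort_grid, sediment_grid, d_table, slope)


def simple_cells(rbs, areas=None, f=None):
    """Minimal cell table for summary-level unit tests."""
    rbs = np.asarray(rbs, dtype=float)
    n = len(rbs)
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "area_km2": np.ones(n) if areas is None else np.asarray(areas, float),
            "rbs_mean": rbs,
            "rbs_lcl": rbs,
            "rbs_ucl": rbs,
            "f_total": np.zeros(n) if f is None else np.asarray(f, float),
            "habitat": ["sand"] * n,
            "term_otter_trawl": 1.0 - rbs,
        }
    )
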