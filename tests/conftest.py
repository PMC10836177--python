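import numpy as np
import pandas as pd
import pytest

from stcar.geo_io import AreaYearPanel, PanelSchema
from stcar.synthetic_region import Scenario, make_lattice, simulate_study


@pytest.fixture(scope="session")
def lattice_4x4():
    return make_lattice(4, 4, cell_size=10_000.0)


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared across read-only tests."""
    return simulate_study(Scenario(nx=5, ny=5, n_years=4, n_facilities=3, seed=101))


def make_toy_panel(K=4, T=3, seed=0, start_year=2010, deaths=None):
    """Minimal valid balanced panel with benign covariates."""
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(K):
        pop = 10_000.0 * (1 + k)
        for t in range(T):
            rows.append(
                {
                    "area_id": f"a{k:03d}",
                    "year": start_year + t,
                    "deaths": int(deaths[k][t]) if deaths is not None else int(rng.poisson(8)),
                    "pop_total": pop,
                    "pop_15plus": 0.8 * pop,
                    "pop_50_59": 0.12 * pop,
                    "pop_60_69": 0.08 * pop,
                    "pop_70_79": 0.05 * pop,
                    "phc_coverage": float(rng.uniform(40, 90)),
                    "ipdm": float(rng.uniform(0.3, 0.9)),
                    "stress_test_rate": float(rng.uniform(0.5, 4)),
                    "echo_rate": float(rng.uniform(1, 8)),
                    "scinti_rate": float(rng.uniform(0.1, 1)),
                    "cath_rate": float(rng.uniform(0.3, 3)),
                    "cardiologist_rate": float(rng.uniform(0.1, 1)),
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def toy_panel():
    return AreaYearPanel(make_toy_panel(), PanelSchema())
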