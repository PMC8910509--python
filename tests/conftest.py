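import numpy as np
import pandas as pd
import pytest

from esvpipe import attribution, synthetic
from esvpipe.fixtures import load_fixtures
from esvpipe.hai import compute_hai
from esvpipe.landuse import tabulate_areas


@pytest.fixture(scope="session")
def paper():
    return load_fixtures()


@pytest.fixture(scope="session")
def small_landscape():
    """A small synthetic study: 8 contiguous zones on a 40x40 grid."""
    scenario = synthetic.default_scenario(11, n_zones=8, grid_shape=(40, 40))
    grids, zones = synthetic.generate_landscape(scenario)
    return scenario, grids, zones


@pytest.fixture(scope="session")
def driver_table(paper):
    """Planted-effect driver table: 30 zones x 4 years, dominant HAI term."""
    scenario = synthetic.default_scenario(23, n_zones=30)
    grids, zones = synthetic.generate_landscape(scenario)
    drivers = synthetic.generate_drivers(scenario, grids, zones)
    areas = pd.concat([tabulate_areas(g, zones) for g in grids],
                      ignore_index=True)
    hai = compute_hai(areas, paper.pi)
    table = drivers.merge(
        hai[["zone", "year", "hai"]].rename(columns={"hai": "HAI"}),
        on=["zone", "year"],
    )
    table["ESV"] = synthetic.planted_response(
        table, scenario.planted_effect, seed=23
    )
    return table[["zone", "year", *attribution.FEATURES, "ESV"]]


@pytest.fixture(scope="session")
def fitted_model(driver_table):
    return attribution.fit_model(
        driver_table, {"n_estimators": 100}, seed=23
    )


@pytest.fixture(scope="session")
def attr_matrix(fitted_model, driver_table):
    return attribution.shapley(fitted_model, driver_table, driver_table)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
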