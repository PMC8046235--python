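import numpy as np
import pytest

from forestct.synthetic_data import ScenarioParams, generate_scenario, paper_margin_fixture


@pytest.fixture(scope="session")
def small_scenario():
    """10 species, 4 of them sharing an engineered overlap cluster."""
    params = ScenarioParams(
        n_species=10,
        overlap_cluster_size=4,
        n_forest_missing=1,
        range_area_km2=(900.0, 2200.0),
    )
    return generate_scenario(params, seed=42)


@pytest.fixture(scope="session")
def margin_fixture():
    return paper_margin_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
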