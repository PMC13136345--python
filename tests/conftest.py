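import numpy as np
import pytest

from landclim import synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """Small but fully featured synthetic study for integration tests."""
    return synth.SyntheticConfig(
        fine_grid_shape=(36, 36),
        coarsen_factor=3,
        n_years=6,
        n_days_per_year=40,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    """Land systems, PFT grids, truth, and climate for the small study."""
    grid_ref, grid_scen, land, comp = synth.generate_pft_grids(small_config)
    truth = synth.make_truth(small_config)
    ds_ref, ds_scen = synth.generate_climate_fields(
        small_config, grid_ref, grid_scen, truth
    )
    return {
        "config": small_config,
        "land": land,
        "composition": comp,
        "grid_ref": grid_ref,
        "grid_scen": grid_scen,
        "truth": truth,
        "ds_ref": ds_ref,
        "ds_scen": ds_scen,
    }
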