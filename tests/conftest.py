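import numpy as np
import pytest

from odast import ScenarioConfig, StudyDimensions, simulate_scenario


@pytest.fixture
def tiny_dims() -> StudyDimensions:
    """Two countries plus rest of world, three age groups, one year."""
    return StudyDimensions(countries=("AA", "BB"), n_ages=3, years=(2007,))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160122)


@pytest.fixture
def tiny_study(tiny_dims):
    """A small simulated study with both report forms and missing blocks."""
    cfg = ScenarioConfig(seed=5, missing_fraction_send=0.3,
                         missing_fraction_recv=0.3, sexonly_fraction=0.3,
                         base_flow=40.0)
    truth, data, od = simulate_scenario(tiny_dims, cfg, n_od_draws=20,
                                        od_dispersion=0.02)
    assert data.mask_agesex.any() and data.mask_sexonly.any()
    return cfg, truth, data, od
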