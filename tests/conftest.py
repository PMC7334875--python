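import numpy as np
import pytest

from cropmap import assign, qc_norm, screen_sim


@pytest.fixture(scope="session")
def default_design():
    return screen_sim.default_screen_design(seed=0)


@pytest.fixture(scope="session")
def small_sim(default_design):
    """A modest default-condition screen shared across read-only tests."""
    params = screen_sim.SimParams(n_cells=3000, seed=11)
    return screen_sim.simulate_screen(default_design, params)


@pytest.fixture(scope="session")
def small_norm(small_sim):
    """QC-filtered and normalized version of the shared screen."""
    filtered, report = qc_norm.qc_filter(small_sim.adata)
    return qc_norm.normalize_log2(filtered), report


@pytest.fixture(scope="session")
def small_assignment(small_sim):
    return assign.assign_guides(small_sim.adata)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
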