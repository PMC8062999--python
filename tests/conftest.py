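import numpy as np
import pytest

from mirswitch import MmiParameters
from mirswitch.tissue import (
    MorphogenConfig,
    cell_model,
    default_initial,
    knockout,
    make_morphogen_field,
    simulate_tissue,
)


@pytest.fixture(scope="session")
def fig4d_left():
    return MmiParameters(n_sites=2, a=(1.0, 10.0), b=(1.0, 1.0), K_scaled=1e-5)


@pytest.fixture(scope="session")
def balanced_two_site():
    return MmiParameters(n_sites=2, a=(1.0, 1.0), b=(1.0, 1.0), K_scaled=1e-5)


def run_tissue(spec, seed=1, cfg=None, t_end=80.0, dt=0.01):
    """Standard tissue run: naive cells with resting miRNA pools."""
    cfg = cfg or MorphogenConfig()
    field = make_morphogen_field(cfg, seed=seed)
    init = default_initial(spec)
    shape = (cfg.n_columns, cfg.n_positions)
    grid = {k: np.full(shape, v) for k, v in init.items()}
    return simulate_tissue(spec, field, t_end=t_end, dt=dt, seed=seed, initial=grid)


@pytest.fixture(scope="session")
def wt_trajectory():
    return run_tissue(cell_model("mmi_S"), seed=1)


@pytest.fixture(scope="session")
def mir27ko_trajectory():
    return run_tissue(knockout(cell_model("mmi_S"), "miR-27"), seed=1)


@pytest.fixture(scope="session")
def mir196ko_trajectory():
    return run_tissue(knockout(cell_model("mmi_S"), "miR-196"), seed=1)
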