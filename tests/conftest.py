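import numpy as np
import pytest

from ismpop import (
    InitialState,
    KineticParameters,
    OpticsParameters,
    simulate_bioprocess,
)
from ismpop.config import default_config


@pytest.fixture(scope="session")
def default_cfg():
    return default_config(seed=0)


@pytest.fixture(scope="session")
def default_trajectory(default_cfg):
    """The 145-h batch -> continuous reference recipe, integrated once."""
    cfg = default_cfg
    return simulate_bioprocess(cfg.kinetics, cfg.events, cfg.init, cfg.t_end, cfg.dt)


@pytest.fixture(scope="session")
def optics():
    return OpticsParameters()


@pytest.fixture()
def quiet_params():
    """All rate constants zero: the culture state is a fixed point."""
    return KineticParameters(
        mu_max=1e-12,  # mu_max must be > 0; negligible
        Ks=0.5, Ko=3.0,
        k_bulge_on=0, k_bulge_off=0, k_bulge_on_base=0, k_bulge_off_base=0,
        k_apo_base=0, k_apo_stress=0, k_nec_base=0, k_nec_stress=0,
        k_late=0, k_pair=0, k_split=0, k_lysis=0, D=0,
    )


@pytest.fixture()
def growth_only_params():
    """Pure exponential growth: no death, no transitions, no consumption."""
    return KineticParameters(
        mu_max=0.04, Ks=0.0, Ko=0.0,
        k_bulge_on=0, k_bulge_off=0, k_bulge_on_base=0, k_bulge_off_base=0,
        k_apo_base=0, k_apo_stress=0, k_nec_base=0, k_nec_stress=0,
        k_late=0, k_pair=0, k_split=0, k_lysis=0, D=0,
        yield_cells_per_g=np.inf,
        ff_rel_threshold=1e9, s_lim=0.0,
    )


@pytest.fixture()
def simple_init():
    return InitialState(
        viable=4.0e5, viable_bulges=0.0, pair=0.0,
        apoptotic=0.0, necrotic=0.0, necrotic_late=0.0,
        substrate=4.5, dissolved_oxygen=30.0,
    )
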