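import numpy as np
import pytest

import h3k27sim as h


@pytest.fixture(scope="session")
def lattice():
    return h.Lattice()


@pytest.fixture(scope="session")
def params():
    return h.ModelParams()


@pytest.fixture(scope="session")
def pcg_profile(lattice):
    return h.make_preset_profile("pcg_target", lattice=lattice)


@pytest.fixture(scope="session")
def active_profile(lattice):
    return h.make_preset_profile("active", lattice=lattice)


@pytest.fixture(scope="session")
def wt_steady_ensemble(pcg_profile, params):
    """Moderate-size WT steady-state ensemble shared across tests."""
    from h3k27sim.observables import steady_state_ensemble

    return steady_state_ensemble(
        pcg_profile, params, n_traj=24, burn_in_cycles=12, sample_cycles=4, seed=101
    )
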