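import numpy as np
import pytest

import voromech as vm
from voromech import mechanics as mech
from voromech.tessellation import EXTERIOR, INTERIOR


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_confined_state():
    """A small (~17 demarcated cells) confined configuration with valid
    reference areas, used for energy/force consistency tests."""
    from dataclasses import replace

    centers = vm.generate_seed_points(9, 9 * 50.0, 0.25, seed=3)
    spec = vm.ConfinementSpec(
        shape="circle", outer_radius=115.0, center=(225.0, 225.0)
    )
    demarc = spec.demarcate(centers.positions)
    cls = np.full(len(centers), EXTERIOR, dtype=object)
    cls[demarc] = INTERIOR
    centers.cell_class = cls
    state = vm.SimulationState(
        centers,
        vm.MechanicsParams(tension_eps=0.5, core_radius=15.0, core_stiffness=5.0),
        spec,
        phase=mech.PHASE_INIT,
    )
    t = state.tessellation
    state.params = replace(
        state.params,
        A0_per_cell=np.where(t.bounded, t.areas, np.nan),
        A0_total=float(np.nansum(np.where(demarc, t.areas, np.nan))),
    )
    centers.mobile = t.bounded.copy()
    return state


@pytest.fixture(scope="session")
def equilibrium_state():
    """One converged default-calibration equilibrium at the radially aligned
    corner of the phase diagram (shared across tests for speed)."""
    return vm.run_equilibrium(
        vm.ConfinementSpec(), g=0.5, rho=0.4, rho_g=1.0, seed=1
    )
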