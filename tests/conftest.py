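import numpy as np
import pytest

from protonsim.fixtures import make_water_tank
from protonsim.transport import DoseGrid, ProtonState, transport_in_phantom


@pytest.fixture(scope="session")
def small_tank():
    """Coarse homogeneous water tank for fast transport tests."""
    return make_water_tank(side=20.0, voxel=1.0)


@pytest.fixture(scope="session")
def pencil_dose(small_tank):
    """100k-history 102.7 MeV pencil-beam dose grid, reused across tests."""
    n = 100_000
    state = ProtonState(
        position=np.tile([0.0, 0.0, -1.0], (n, 1)),
        direction=np.tile([0.0, 0.0, 1.0], (n, 1)),
        kinetic_energy=np.full(n, 102.7),
    )
    dose = DoseGrid((-10.0, -10.0, 0.0), (0.5, 0.5, 0.1), (40, 40, 120))
    return transport_in_phantom(state, small_tank, dose, seed=1234)


def pencil_state(n, energy=102.7, z=-1.0):
    return ProtonState(
        position=np.tile([0.0, 0.0, z], (n, 1)),
        direction=np.tile([0.0, 0.0, 1.0], (n, 1)),
        kinetic_energy=np.full(n, energy),
    )
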