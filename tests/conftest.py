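import numpy as np
import pytest

from patchymd.engine import State, thermalize
from patchymd.model import build_mixture, build_species_catalog
from patchymd.potential import ForceField
from patchymd.rigid import random_unit_quaternions


@pytest.fixture(scope="session")
def catalog():
    return build_species_catalog()


@pytest.fixture(scope="session")
def valency_driven():
    return build_mixture("valency_driven", 8)


@pytest.fixture(scope="session")
def valency_driven_ff(valency_driven):
    return ForceField(valency_driven)


def lattice_state(ff, n_per_species, box_edge, rng, temperature=None):
    """Cubic-lattice configuration covering every species, optionally thermalized."""
    names = ff.species_names
    n = n_per_species * len(names)
    m = int(np.ceil(n ** (1 / 3)))
    pts = np.array(
        [(i, j, k) for i in range(m) for j in range(m) for k in range(m)][:n], dtype=float
    )
    box = np.array([box_edge] * 3, dtype=float)
    sidx = np.repeat(np.arange(len(names)), n_per_species)
    rng.shuffle(sidx)
    state = State(
        box=box,
        positions=(pts + 0.5) * (box / m),
        orientations=random_unit_quaternions(n, rng),
        velocities=np.zeros((n, 3)),
        ang_momenta=np.zeros((n, 3)),
        species_index=sidx,
        species_names=names,
    )
    if temperature is not None:
        thermalize(state, temperature, rng)
    return state
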