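import numpy as np
import pytest

from iwmgb.assembler import prepare_geometry
from iwmgb.fixtures import born_ion_parameter_set, make_born_ion, make_toy_set
from iwmgb.model_io import Atom, Molecule, load_parameter_set


@pytest.fixture(scope="session")
def nc_params():
    return load_parameter_set("nc")


@pytest.fixture(scope="session")
def wc_params():
    return load_parameter_set("wc")


@pytest.fixture(scope="session")
def toy_molecules():
    return make_toy_set(20, seed=7)


@pytest.fixture(scope="session")
def born_fixture():
    """Unit charge in a 4 Å sphere with analytic icosphere surfaces."""
    mol, meshes = make_born_ion(1.0, 4.0, probe_radius=0.8, subdivisions=4)
    params = born_ion_parameter_set(4.0, probe_radius=0.8)
    return mol, meshes, params


@pytest.fixture(scope="session")
def toy_geometries(toy_molecules, nc_params):
    """Shared surfaces/SCD/Born-radii geometry for the NC toy set."""
    return [prepare_geometry(m, nc_params) for m in toy_molecules]


def single_atom(element="C", radius=2.0, charge=0.0):
    return Molecule(
        "single", [Atom(0, element, np.zeros(3), charge, radius)]
    )
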