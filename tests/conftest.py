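import numpy as np
import pytest

from driftchem import (
    Atom,
    BufferGasModel,
    CandidateStructure,
    Ensemble,
    InstrumentConfig,
    nitrogen_gas,
)


@pytest.fixture(scope="session")
def n2():
    return nitrogen_gas()


@pytest.fixture(scope="session")
def single_site_gas():
    """One neutral LJ site: makes the ion-gas problem centrally symmetric
    for single-atom ions, enabling oracle comparisons."""
    return BufferGasModel(
        name="probe",
        mass=28.0,
        temperature=298.0,
        sites=((0.0, 0.0, 0.30, 3.0),),
        collision_radius=1.7,
    )


def make_atom(x=0.0, y=0.0, z=0.0, q=0.0, eps=0.5, sigma=3.5, element="X"):
    return Atom(element, (x, y, z), q, lj_epsilon=eps, lj_sigma=sigma)


@pytest.fixture
def lone_atom_ion():
    return CandidateStructure(
        id="s1", molecule="M", charge_state=0, site_label="none",
        atoms=[make_atom()],
    )


@pytest.fixture
def two_candidate_ensemble():
    """Two candidates mirroring a two-conformer monoprotonated ensemble:
    CCS 192.9 Å² at G=0 and 187.2 Å² at G=+4 kJ/mol."""
    a = CandidateStructure(
        id="conf1", molecule="AQ", charge_state=1, site_label="a",
        atoms=[make_atom(q=1.0)], g_aq=0.0, g_gas=0.0, ccs_calc=192.9,
    )
    b = CandidateStructure(
        id="conf2", molecule="AQ", charge_state=1, site_label="a",
        atoms=[make_atom(q=1.0)], g_aq=4.0, g_gas=4.0, ccs_calc=187.2,
    )
    return Ensemble(molecule="AQ", candidates=[a, b])


@pytest.fixture(scope="session")
def instrument():
    return InstrumentConfig()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
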