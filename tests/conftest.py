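import numpy as np
import pytest

from ligmigrate import AtomRecord, FixtureSpec, Structure, make_ligand, make_receptor


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def toy_atom(serial=1, pos=(0.0, 0.0, 0.0), element="C", charge=0.0, res=1, chain="A",
             name=None, mass=12.011):
    return AtomRecord(
        serial=serial,
        name=name or element,
        element=element,
        residue_name="TOY",
        residue_seq=res,
        chain_id=chain,
        position=np.asarray(pos, dtype=float),
        mass=mass,
        charge=charge,
    )


@pytest.fixture
def two_atom_structure():
    return Structure(
        [toy_atom(1, (-1.0, 0.0, 0.0)), toy_atom(2, (1.0, 0.0, 0.0), res=2)],
        label="pair",
    )


@pytest.fixture
def acidic_barrel():
    return make_receptor(FixtureSpec("acidic_barrel", has_second_site=True, seed=7))


@pytest.fixture
def neutral_barrel():
    return make_receptor(FixtureSpec("neutral_barrel", has_second_site=True, seed=7))


@pytest.fixture
def pocket_receptor():
    return make_receptor(FixtureSpec("pocket_receptor", seed=7))


@pytest.fixture
def ligand_plus1():
    return make_ligand("amine_protonated", seed=7)
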