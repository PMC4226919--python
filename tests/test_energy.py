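"""Nonbonded energy model: closed forms, brute-force oracles, invariances."""

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

from ligmigrate import (
    FixtureSpec,
    ForceFieldParams,
    Structure,
    interaction_energy,
    make_competition_fixture,
    make_ligand,
    make_receptor,
    pair_energy,
    structure_energy,
    system_energy,
)
from ligmigrate.energy import DEFAULT_ATOM_CLASSES
from ligmigrate.errors import DomainError
from ligmigrate.structures import CompetitiveSystem, LigandPose

from conftest import toy_atom


def lj_sigma(el_i, el_j, params=None):
    classes = (params or ForceFieldParams()).atom_classes
    return 0.5 * (classes[el_i][1] + classes[el_j][1])


def brute_pair(ai, aj, params):
    """Independent scalar re-derivation of the shifted LJ + Coulomb pair term."""
    r = float(np.linalg.norm(ai.position - aj.position))
    rc = params.nonbonded_cutoff
    if r >= rc:
        return 0.0
    ei, si = params.atom_classes[ai.element]
    ej, sj = params.atom_classes[aj.element]
    eps = (ei * ej) ** 0.5
    sig = 0.5 * (si + sj)

    def raw(rr):
        lj = 4 * eps * ((sig / rr) ** 12 - (sig / rr) ** 6)
        if params.dielectric_model == "distance_dependent":
            coul = params.coulomb_constant * ai.charge * aj.charge / (
                params.dielectric_scale * rr * rr
            )
        else:
            coul = params.coulomb_constant * ai.charge * aj.charge / (
                params.dielectric_scale * rr
            )
        return lj + coul

    return raw(r) - raw(rc)


class TestPairEnergy:
    def test_lj_minimum_closed_form(self):
        """At r = 2^(1/6) sigma with zero charges the LJ term equals -epsilon
        (up to the small constant cutoff shift)."""
        params = ForceFieldParams()
        eps, sig = params.atom_classes["C"]
        r_star = 2 ** (1 / 6) * sig
        ai = toy_atom(1, (0, 0, 0))
        aj = toy_atom(2, (r_star, 0, 0), res=2)
        shift = 4 * eps * ((sig / params.nonbonded_cutoff) ** 12
                           - (sig / params.nonbonded_cutoff) ** 6)
        assert pair_energy(ai, aj, params) == pytest.approx(-eps - shift, rel=1e-12)

    def test_zero_beyond_cutoff(self):
        ai = toy_atom(1, (0, 0, 0), charge=1.0)
        aj = toy_atom(2, (12.0, 0, 0), charge=-1.0, res=2)
        assert pair_energy(ai, aj) == 0.0

    def test_like_charges_repel(self):
        params = ForceFieldParams(
            atom_classes={**DEFAULT_ATOM_CLASSES, "C": (0.0, 3.75)}
        )
        ai = toy_atom(1, (0, 0, 0), charge=1.0)
        aj = toy_atom(2, (5.0, 0, 0), charge=1.0, res=2)
        assert pair_energy(ai, aj, params) > 0

    def test_opposite_charges_attract(self):
        params = ForceFieldParams(
            atom_classes={**DEFAULT_ATOM_CLASSES, "C": (0.0, 3.75)}
        )
        ai = toy_atom(1, (0, 0, 0), charge=-1.0)
        aj = toy_atom(2, (5.0, 0, 0), charge=1.0, res=2)
        assert pair_energy(ai, aj, params) < 0

    def test_zero_separation_is_singular(self):
        ai = toy_atom(1, (0, 0, 0))
        aj = toy_atom(2, (0, 0, 0), res=2)
        with pytest.raises(DomainError):
            pair_energy(ai, aj)

    def test_continuity_at_cutoff(self):
        params = ForceFieldParams()
        rc = params.nonbonded_cutoff
        ai = toy_atom(1, (0, 0, 0), charge=0.5)
        just_in = toy_atom(2, (rc - 1e-7, 0, 0), charge=-0.5, res=2)
        assert abs(pair_energy(ai, just_in, params)) < 1e-4


class TestStructureEnergy:
    def test_single_atom_zero(self):
        assert structure_energy(Structure([toy_atom(1)])) == 0.0

    def test_same_residue_pair_excluded(self):
        st_ = Structure([toy_atom(1, (0, 0, 0)), toy_atom(2, (1.0, 0, 0), res=1)])
        assert structure_energy(st_) == 0.0

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(3)
        params = ForceFieldParams()
        atoms = [
            toy_atom(
                i + 1,
                rng.uniform(2, 9, size=3),
                element=rng.choice(["C", "N", "O"]),
                charge=rng.uniform(-1, 1),
                res=i + 1,
            )
            for i in range(6)
        ]
        st_ = Structure(atoms)
        expected = sum(
            brute_pair(atoms[i], atoms[j], params)
            for i in range(6)
            for j in range(i + 1, 6)
        )
        assert structure_energy(st_, params) == pytest.approx(expected, abs=1e-9)


class TestInteractionEnergy:
    def test_far_ligand_zero_interaction(self, acidic_barrel):
        lig = make_ligand("imidazole_protonated")
        far = lig.translated(np.array([500.0, 0, 0]))
        br = interaction_energy(acidic_barrel, far)
        assert br.e_interaction == 0.0

    def test_decomposition_identity_and_cross_pair_oracle(self, rng):
        params = ForceFieldParams()
        rec_atoms = [
            toy_atom(i + 1, rng.uniform(0, 8, 3), charge=rng.uniform(-1, 1), res=i + 1)
            for i in range(5)
        ]
        lig_atoms = [
            toy_atom(
                i + 1, rng.uniform(3, 10, 3), charge=rng.uniform(-1, 1),
                res=1, chain="L",
            )
            for i in range(3)
        ]
        rec, lig = Structure(rec_atoms), Structure(lig_atoms)
        br = interaction_energy(rec, lig, params)
        assert br.e_interaction == br.e_complex - (br.e_receptor + br.e_ligand)
        expected_cross = sum(
            brute_pair(a, b, params) for a in rec_atoms for b in lig_atoms
        )
        assert br.e_interaction == pytest.approx(expected_cross, abs=1e-9)

    def test_opposite_charge_site_attracts(self):
        params = ForceFieldParams(
            atom_classes={**DEFAULT_ATOM_CLASSES, "C": (0.0, 3.75)}
        )
        rec = Structure([toy_atom(1, (0, 0, 0), charge=-1.0)])
        lig = Structure([toy_atom(1, (5.0, 0, 0), charge=1.0, chain="L")])
        assert interaction_energy(rec, lig, params).e_interaction < 0

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_rigid_transform_invariance(self, seed):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(seed)
        rec = Structure(
            [toy_atom(i + 1, rng.uniform(0, 6, 3), charge=rng.uniform(-1, 1), res=i + 1)
             for i in range(4)]
        )
        lig = Structure(
            [toy_atom(i + 1, rng.uniform(2, 8, 3), charge=rng.uniform(-1, 1),
                      res=1, chain="L") for i in range(2)]
        )
        e0 = interaction_energy(rec, lig).e_interaction
        R = Rotation.random(random_state=seed).as_matrix()
        t = rng.normal(scale=20, size=3)
        e1 = interaction_energy(
            rec, lig,
            receptor_coords=rec.coords @ R.T + t,
            ligand_coords=lig.coords @ R.T + t,
        ).e_interaction
        # relative tolerance: steep r^-12 wall amplifies coordinate round-off
        assert e1 == pytest.approx(e0, rel=1e-6, abs=1e-6)


class TestSystemEnergy:
    def test_midpoint_symmetry(self):
        """A point ligand midway between two identical point receptors sees
        equal interaction energies (exact symmetry requires congruence about
        the midpoint, which point receptors guarantee)."""
        rec_a = Structure([toy_atom(1, (0, 0, 0), charge=-1.0)])
        rec_b = Structure([toy_atom(1, (50, 3, -2), charge=-1.0)])
        bead = Structure([toy_atom(1, (0, 0, 0), charge=1.0, chain="L")])
        from ligmigrate import assemble_system

        system = assemble_system(rec_a, rec_b, [bead], 10.0, 5.0, seed=0)
        e_a, e_b = system_energy(system, 0)
        assert e_a == pytest.approx(e_b, rel=1e-12)
        assert e_a < 0  # opposite charges at 5 Å attract

    def test_beyond_cutoff_of_b_only(self, acidic_barrel, pocket_receptor):
        from ligmigrate import assemble_system

        lig = make_ligand("amine_protonated")
        system = assemble_system(acidic_barrel, pocket_receptor, [lig], 100.0, 50.0, 0)
        # park ligand 5 Å from receptor a's surface, far from b
        system.ligands[0].coords = lig.coords + (system.com_a() + np.array([0, 0, 14.0]))
        e_a, e_b = system_energy(system, 0)
        assert e_b == 0.0
        assert e_a != 0.0

    def test_label_swap_swaps_energies(self, acidic_barrel, pocket_receptor):
        from ligmigrate import assemble_system

        lig = make_ligand("imidazole_protonated")
        s1 = assemble_system(acidic_barrel, pocket_receptor, [lig], 30.0, 18.0, 5)
        e_a1, e_b1 = system_energy(s1, 0)
        s2 = CompetitiveSystem(
            receptor_a=s1.receptor_b,
            receptor_b=s1.receptor_a,
            ligands=[LigandPose(lig, s1.ligands[0].coords.copy())],
            separation=s1.separation,
            ligand_offset=s1.ligand_offset,
        )
        e_a2, e_b2 = system_energy(s2, 0)
        assert (e_a2, e_b2) == pytest.approx((e_b1, e_a1), abs=1e-12)

    def test_matches_cross_pair_enumeration(self):
        params = ForceFieldParams()
        rec_a = Structure([toy_atom(1, (0, 0, 0), charge=-1.0)])
        rec_b = Structure([toy_atom(1, (14.0, 0, 0), charge=0.5)])
        lig_atom = toy_atom(1, (6.0, 1.0, 0), charge=1.0, chain="L")
        system = CompetitiveSystem(
            receptor_a=rec_a,
            receptor_b=rec_b,
            ligands=[LigandPose(Structure([lig_atom]), np.array([[6.0, 1.0, 0]]))],
            separation=14.0,
            ligand_offset=7.0,
        )
        e_a, e_b = system_energy(system, 0, params)
        assert e_a == pytest.approx(brute_pair(rec_a.atoms[0], lig_atom, params), abs=1e-12)
        assert e_b == pytest.approx(brute_pair(rec_b.atoms[0], lig_atom, params), abs=1e-12)

    def test_invalid_index_rejected(self, acidic_barrel, pocket_receptor):
        from ligmigrate import assemble_system

        system = assemble_system(
            acidic_barrel, pocket_receptor, [make_ligand()], 30.0, 18.0, 0
        )
        with pytest.raises(DomainError):
            system_energy(system, 3)


def test_matched_control_discrimination():
    """Same pose offset at the acidic vs neutral barrel rim: the +1 ligand
    interacts strictly more favourably with the charged rim."""
    acidic = make_receptor(FixtureSpec("acidic_barrel", seed=4))
    neutral = make_receptor(FixtureSpec("neutral_barrel", seed=4))
    np.testing.assert_array_equal(acidic.coords, neutral.coords)
    lig = make_ligand("amine_protonated")
    # pose 4 Å above the open-mouth rim, identical relative to both barrels
    pose = lig.coords - lig.coords.mean(0) + np.array([0.0, 0.0, 10.0])
    e_acidic = interaction_energy(acidic, lig, ligand_coords=pose).e_interaction
    e_neutral = interaction_energy(neutral, lig, ligand_coords=pose).e_interaction
    assert e_acidic < e_neutral
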