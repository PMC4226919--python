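"""Monte Carlo propagator: moves, minimizer, Metropolis, spawning, chains."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ligmigrate import (
    FixtureSpec,
    ForceFieldParams,
    MCConfig,
    Structure,
    make_competition_fixture,
    make_receptor,
    metropolis_accept,
    minimize_ligand,
    perturb_ligand,
    run_chain,
    sample_side_chains,
    spawn_check_and_constrain,
)
from ligmigrate.mc_engine import Frame
from ligmigrate.errors import DomainError

from conftest import toy_atom


class TestPerturbLigand:
    def test_zero_magnitudes_identity(self, rng, ligand_plus1):
        out = perturb_ligand(ligand_plus1.coords, 0.0, 0.0, rng)
        np.testing.assert_array_equal(out, ligand_plus1.coords)

    @given(seed=st.integers(0, 500))
    @settings(max_examples=30, deadline=None)
    def test_translation_bounded_and_rigid(self, seed):
        from ligmigrate import make_ligand

        lig = make_ligand("deprotonated")
        r = np.random.default_rng(seed)
        out = perturb_ligand(lig.coords, 12.0, 0.2, r)
        # rigidity: all pairwise distances preserved
        def pdist(x):
            return np.linalg.norm(x[:, None] - x[None, :], axis=-1)

        np.testing.assert_allclose(pdist(out), pdist(lig.coords), atol=1e-9)
        # centroid displacement bounded by tra_r (rotation preserves centroid)
        shift = np.linalg.norm(out.mean(0) - lig.coords.mean(0))
        assert shift <= 12.0 + 1e-9


class TestSampleSideChains:
    def test_far_ligand_leaves_receptor_untouched(self, rng, acidic_barrel):
        lig_far = np.array([[500.0, 0, 0]])
        out = sample_side_chains(acidic_barrel, lig_far, sprad=6.0, rng=rng)
        assert out is acidic_barrel

    def test_locality_outside_selection(self, rng, acidic_barrel):
        # ligand close to the rim: only residues within sprad may move
        rim = acidic_barrel.coords[acidic_barrel.coords[:, 2].argmax()]
        lig = rim[None, :] + np.array([[0.0, 0.0, 2.0]])
        out = sample_side_chains(acidic_barrel, lig, sprad=6.0, rng=rng)
        d = np.sqrt((((acidic_barrel.coords[:, None, :] - lig[None, :, :]) ** 2).sum(-1)).min(1))
        far = d > 6.0
        np.testing.assert_array_equal(out.coords[far], acidic_barrel.coords[far])
        assert not np.array_equal(out.coords, acidic_barrel.coords)

    def test_no_internal_clashes_after_sampling(self, rng, acidic_barrel):
        rim = acidic_barrel.coords[acidic_barrel.coords[:, 2].argmax()]
        lig = rim[None, :] + np.array([[0.0, 0.0, 2.0]])
        out = sample_side_chains(acidic_barrel, lig, sprad=8.0, rng=rng, max_disp=1.0)
        d = np.linalg.norm(out.coords[:, None] - out.coords[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 1.5 or np.array_equal(out.coords, acidic_barrel.coords)


class TestMinimizeLigand:
    def test_descent_contract(self, rng):
        def bumpy(x):
            c = x.mean(0)
            return float(np.sin(c).sum() + 0.1 * (c**2).sum())

        start = rng.normal(scale=3, size=(4, 3))
        out, e = minimize_ligand(start, bumpy, max_iters=20)
        assert e <= bumpy(start) + 1e-12

    def test_converges_to_lj_minimum(self):
        """1-bead ligand vs 1-site receptor with zero charges: the minimizer
        must find the closed-form LJ minimum separation r* = 2^(1/6) sigma."""
        params = ForceFieldParams()
        _, sigma = params.atom_classes["C"]
        rec = Structure([toy_atom(1, (0, 0, 0))])
        from ligmigrate.energy import interaction_energy

        lig = Structure([toy_atom(1, (6.0, 0, 0), chain="L")])

        def efn(x):
            return interaction_energy(rec, lig, params, ligand_coords=x).e_interaction

        out, e = minimize_ligand(
            np.array([[6.0, 0.0, 0.0]]), efn, max_iters=60, tol=1e-5, initial_step=1.0
        )
        r_star = 2 ** (1 / 6) * sigma
        assert np.linalg.norm(out[0]) == pytest.approx(r_star, abs=2e-3)

    def test_local_minimum_stays_put(self):
        def quad(x):
            return float(((x.mean(0)) ** 2).sum())

        out, e = minimize_ligand(np.zeros((2, 3)), quad, max_iters=10)
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_nonfinite_start_rejected(self):
        with pytest.raises(DomainError):
            minimize_ligand(np.zeros((1, 3)), lambda x: float("nan"))


class TestMetropolis:
    def test_downhill_always_accepts(self, rng):
        assert all(
            metropolis_accept(-5.0, -1.0, kT, rng) for kT in (0.0, 0.1, 10.0)
        )
        assert metropolis_accept(2.0, 2.0, 0.0, rng)  # equal energy accepts

    def test_greedy_limit_rejects_uphill(self, rng):
        for _ in range(100):
            e_ref = rng.normal()
            e_new = e_ref + abs(rng.normal()) + 1e-12
            assert not metropolis_accept(e_new, e_ref, 0.0, rng)

    def test_boltzmann_rate_at_delta_equals_kT(self):
        rng = np.random.default_rng(77)
        kT = 0.596
        n = 100_000
        acc = sum(metropolis_accept(kT, 0.0, kT, rng) for _ in range(n))
        assert acc / n == pytest.approx(np.exp(-1), abs=0.01)

    def test_acceptance_monotone_in_kT(self):
        rates = []
        for kT in (0.2, 0.6, 1.5, 5.0):
            rng = np.random.default_rng(5)
            rates.append(
                sum(metropolis_accept(1.0, 0.0, kT, rng) for _ in range(20000)) / 20000
            )
        assert rates == sorted(rates)


class TestSpawning:
    def _frame(self, da, db, spawned=None):
        return Frame(0, np.zeros((1, 3)), 0.0, 0.0, 0.0, da, db, spawned=spawned)

    def test_far_ligand_unconstrained(self, acidic_barrel, pocket_receptor):
        from ligmigrate import assemble_system, make_ligand

        system = assemble_system(
            acidic_barrel, pocket_receptor, [make_ligand()], 67.0, 42.0, 0
        )
        assert spawn_check_and_constrain(self._frame(42.0, 42.0), system, MCConfig()) is None

    def test_capture_within_trigger(self, acidic_barrel, pocket_receptor):
        from ligmigrate import assemble_system, make_ligand

        system = assemble_system(
            acidic_barrel, pocket_receptor, [make_ligand()], 67.0, 42.0, 0
        )
        cfg = MCConfig()
        assert spawn_check_and_constrain(self._frame(9.0, 60.0), system, cfg) == "a"
        assert spawn_check_and_constrain(self._frame(60.0, 9.0), system, cfg) == "b"
        # already-captured token is sticky
        assert spawn_check_and_constrain(self._frame(60.0, 60.0, "a"), system, cfg) == "a"

    def test_constrained_chain_respects_radius(self):
        """Individual-mode chain: every accepted frame after capture stays
        within the spawning sphere."""
        system = make_competition_fixture(
            FixtureSpec("acidic_barrel", has_second_site=True, seed=1),
            FixtureSpec("pocket_receptor", seed=1),
            "amine_protonated",
            seed=1,
            scaled_down=True,
        )
        system.receptor_b = None
        cfg = MCConfig(steps=400, seed=9)
        traj = run_chain(system, 0, cfg, chain_id=0, spawning=True)
        seen_capture = False
        for fr in traj.frames:
            if fr.spawned is not None:
                if seen_capture:  # frames after the capturing frame
                    assert fr.dist_to_a <= cfg.spawn_radius + 1e-9
                seen_capture = True


class TestRunChain:
    def _system(self, state="amine_protonated"):
        return make_competition_fixture(
            FixtureSpec("acidic_barrel", has_second_site=True, seed=1),
            FixtureSpec("pocket_receptor", seed=1),
            state,
            seed=1,
            scaled_down=True,
        )

    def test_frozen_proposal_keeps_start(self):
        system = self._system()
        cfg = MCConfig(steps=1, tra_r=0.0, rot_r=0.0, seed=0)
        traj = run_chain(system, 0, cfg)
        assert len(traj.frames) <= 2
        np.testing.assert_allclose(
            traj.frames[0].coords, system.ligands[0].coords, atol=1e-12
        )

    def test_same_seed_reproducible(self):
        system = self._system()
        cfg = MCConfig(steps=120, seed=21)
        t1 = run_chain(system, 0, cfg, chain_id=3, spawning=False)
        t2 = run_chain(system, 0, cfg, chain_id=3, spawning=False)
        assert len(t1.frames) == len(t2.frames)
        for f1, f2 in zip(t1.frames, t2.frames):
            np.testing.assert_array_equal(f1.coords, f2.coords)
            assert f1.e_interaction == f2.e_interaction

    def test_greedy_energy_never_increases_at_zero_kT(self):
        system = self._system()
        cfg = MCConfig(steps=200, temperature_kT=0.0, seed=4)
        traj = run_chain(system, 0, cfg, spawning=False)
        energies = [fr.e_interaction for fr in traj.frames]
        assert all(e2 <= e1 + 1e-9 for e1, e2 in zip(energies, energies[1:]))

    def test_two_state_occupancy_matches_boltzmann(self):
        """Two-well toy landscape (depths -2 kT and -5 kT): long-run
        occupancy ratio must match the Boltzmann factor e^3 within 3
        standard errors across replicate chains."""
        kT = 0.596
        e0, e1 = -2 * kT, -5 * kT
        ratios = []
        for rep in range(10):
            rng = np.random.default_rng(1000 + rep)
            state = 0
            counts = [0, 0]
            for _ in range(20_000):
                proposal = 1 - state
                e_new, e_ref = (e1, e0) if proposal == 1 else (e0, e1)
                if metropolis_accept(e_new, e_ref, kT, rng):
                    state = proposal
                counts[state] += 1
            ratios.append(counts[1] / counts[0])
        mean = np.mean(ratios)
        se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert abs(mean - np.e**3) <= 3 * se
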