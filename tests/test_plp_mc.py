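import math

import numpy as np
import pytest

from pharmdock.core_chem import Atom, MolecularGraph, PLPAtomClass, rmsd
from pharmdock.plp_mc import (DEFAULT_PLP, MCConfig, PLPPiece, ReceptorPLP,
                              StepSizes, adapt_step_sizes, ligand_torsions,
                              mc_optimize, metropolis_decide, plp_pair_energy,
                              plp_total, propose_move, torsion_scale)
from pharmdock.pose_sampler import Pose

from conftest import carbon_chain


class TestPairPotential:
    @pytest.mark.parametrize("label", ["HBOND", "STERIC"])
    def test_knot_values(self, label):
        p = DEFAULT_PLP.piece(label)
        assert plp_pair_energy(0.0, label) == pytest.approx(p.F)
        assert plp_pair_energy(p.A, label) == pytest.approx(0.0, abs=1e-12)
        assert plp_pair_energy(p.B, label) == pytest.approx(p.E)
        assert plp_pair_energy(p.C, label) == pytest.approx(p.E)
        assert plp_pair_energy(p.D, label) == pytest.approx(0.0, abs=1e-12)
        assert plp_pair_energy(p.D + 1.0, label) == 0.0

    @pytest.mark.parametrize("label", ["HBOND", "STERIC"])
    def test_continuity_at_all_knots(self, label):
        p = DEFAULT_PLP.piece(label)
        for knot in (p.A, p.B, p.C, p.D):
            left = plp_pair_energy(knot - 1e-9, label)
            right = plp_pair_energy(knot + 1e-9, label)
            assert abs(left - right) < 1e-6

    def test_descending_ramp_midpoint(self):
        p = DEFAULT_PLP.hbond
        mid = 0.5 * (p.C + p.D)
        assert plp_pair_energy(mid, "HBOND") == pytest.approx(p.E / 2, abs=1e-12)

    def test_invalid_params_rejected_at_construction(self):
        with pytest.raises(ValueError):
            PLPPiece(3.0, 2.0, 4.0, 5.0, -1.0, 20.0)
        with pytest.raises(ValueError):
            PLPPiece(1.0, 2.0, 3.0, 4.0, 1.0, 20.0)


def single_atom_receptor(element="C", pos=(0.0, 0.0, 0.0)):
    return ReceptorPLP.from_graph(MolecularGraph([Atom(element, np.array(pos))], [], "r"))


class TestTotalEnergy:
    def test_far_ligand_zero(self):
        rec = single_atom_receptor()
        e = plp_total(np.array([[100.0, 0, 0]]), [PLPAtomClass.NONPOLAR], rec)
        assert e == 0.0

    def test_single_steric_pair_well_depth(self):
        rec = single_atom_receptor()
        b = DEFAULT_PLP.steric.B
        e = plp_total(np.array([[b, 0, 0]]), [PLPAtomClass.NONPOLAR], rec)
        assert e == pytest.approx(DEFAULT_PLP.steric.E)

    def test_hbond_pair_uses_hbond_parameters(self):
        rec = single_atom_receptor("O")  # bare O: acceptor class
        b = DEFAULT_PLP.hbond.B
        e = plp_total(np.array([[b, 0, 0]]), [PLPAtomClass.DONOR], rec)
        assert e == pytest.approx(DEFAULT_PLP.hbond.E)

    def test_translation_invariance(self, toy):
        rec = ReceptorPLP.from_graph(toy.receptor)
        from pharmdock.core_chem import assign_plp_class

        heavy = toy.ligand.heavy_indices()
        classes = [assign_plp_class(i, toy.ligand) for i in heavy]
        coords = toy.planted_pose[heavy]
        e0 = plp_total(coords, classes, rec)
        # moving ligand and receptor together changes nothing
        rec2 = ReceptorPLP(rec.coords + [3.0, -1.0, 2.0], rec.classes)
        e1 = plp_total(coords + [3.0, -1.0, 2.0], classes, rec2)
        assert e1 == pytest.approx(e0, abs=1e-12)


class TestTorsionScale:
    def test_worked_examples(self):
        assert torsion_scale(4) == pytest.approx(0.575, abs=1e-12)
        assert torsion_scale(8) == pytest.approx(0.15, abs=1e-12)
        assert 60.0 * torsion_scale(4) == pytest.approx(34.5, abs=1e-9)
        assert 60.0 * torsion_scale(8) == pytest.approx(9.0, abs=1e-9)

    def test_saturates_beyond_nmax(self):
        assert torsion_scale(9) == 0.15
        assert torsion_scale(30) == 0.15

    def test_small_branch_limit(self):
        # formula tends to 1 (no damping) as the branch vanishes
        assert torsion_scale(1) < 1.0
        val = (1 + math.cos(math.pi * 1e-9 / 8)) * 0.5 * 0.85 + 0.15
        assert val == pytest.approx(1.0, abs=1e-9)

    def test_invalid_branch(self):
        with pytest.raises(ValueError):
            torsion_scale(0)


class TestMetropolis:
    def test_improvement_always_accepted(self):
        cfg = MCConfig(seed=0)
        rng = np.random.default_rng(0)
        for _ in range(100):
            assert metropolis_decide(-5.0, -4.0, -1.0, 1.0, cfg, rng) == "ACCEPT"

    def test_leash_forces_reset(self):
        cfg = MCConfig()
        rng = np.random.default_rng(0)
        assert metropolis_decide(-100.0, -1.0, -1.0, 3.6, cfg, rng) == "RESET"

    def test_equal_score_always_accepted(self):
        cfg = MCConfig()
        rng = np.random.default_rng(0)
        for _ in range(100):
            assert metropolis_decide(-1.0, -5.0, -1.0, 1.0, cfg, rng) == "ACCEPT"

    def test_greedy_limit_at_low_temperature(self):
        cfg = MCConfig(temperature=1e-9)
        rng = np.random.default_rng(1)
        for _ in range(200):
            assert metropolis_decide(-0.999, -5.0, -1.0, 1.0, cfg, rng) == "REJECT"

    def test_acceptance_frequency_matches_boltzmann(self):
        """Empirical acceptance of a fixed uphill move tracks exp(-dE/RT)."""
        cfg = MCConfig(seed=0)
        delta = cfg.rt / cfg.energy_scale  # one RT uphill -> P = 1/e
        p_expected = math.exp(-1.0)
        rng = np.random.default_rng(12345)
        n = 10_000
        accepted = sum(
            metropolis_decide(-1.0 + delta, -5.0, -1.0, 1.0, cfg, rng) == "ACCEPT"
            for _ in range(n)
        )
        sigma = math.sqrt(p_expected * (1 - p_expected) / n)
        assert abs(accepted / n - p_expected) < 3 * sigma


class TestStepAdaptation:
    def test_low_rate_shrinks(self):
        cfg = MCConfig()
        sizes = StepSizes(0.5, 15.0, 60.0)
        out = adapt_step_sizes([True] * 30 + [False] * 70, sizes, cfg)
        assert out.translation < sizes.translation
        assert out.rotation < sizes.rotation
        assert out.torsion < sizes.torsion

    def test_in_band_unchanged(self):
        cfg = MCConfig()
        sizes = StepSizes(0.5, 15.0, 60.0)
        out = adapt_step_sizes([True] * 50 + [False] * 50, sizes, cfg)
        assert (out.translation, out.rotation, out.torsion) == (0.5, 15.0, 60.0)

    def test_growth_clamps_at_upper_bound(self):
        cfg = MCConfig()
        sizes = StepSizes(cfg.step_translation, cfg.step_rotation, cfg.step_torsion)
        history = [True] * 100
        for _ in range(100):
            sizes = adapt_step_sizes(history, sizes, cfg)
        assert sizes.translation == pytest.approx(cfg.clamp_high * cfg.step_translation)
        again = adapt_step_sizes(history, sizes, cfg)
        assert again.translation == sizes.translation


class TestProposeMove:
    def test_zero_sizes_identity(self):
        mol = carbon_chain(6)
        rng = np.random.default_rng(0)
        out = propose_move(mol.coords, ligand_torsions(mol),
                           StepSizes(0.0, 0.0, 0.0), rng, MCConfig())
        np.testing.assert_allclose(out, mol.coords, atol=1e-12)

    def test_rigid_ligand_distances_preserved(self, benzene):
        rng = np.random.default_rng(1)
        out = propose_move(benzene.coords, ligand_torsions(benzene),
                           StepSizes(0.5, 15.0, 60.0), rng, MCConfig())
        d_in = np.linalg.norm(benzene.coords[:, None] - benzene.coords[None, :], axis=2)
        d_out = np.linalg.norm(out[:, None] - out[None, :], axis=2)
        np.testing.assert_allclose(d_out, d_in, atol=1e-9)
        assert not np.allclose(out, benzene.coords)

    def test_bond_lengths_preserved_with_torsions(self):
        mol = carbon_chain(8)
        rng = np.random.default_rng(2)
        out = propose_move(mol.coords, ligand_torsions(mol),
                           StepSizes(0.5, 15.0, 60.0), rng, MCConfig())
        for b in mol.bonds:
            d0 = np.linalg.norm(mol.coords[b.i] - mol.coords[b.j])
            d1 = np.linalg.norm(out[b.i] - out[b.j])
            assert d1 == pytest.approx(d0, abs=1e-9)

    def test_bulky_branch_damped(self):
        """A torsion with an 8-heavy-atom branch turns by at most 0.15 x max."""
        mol = carbon_chain(18)  # central bond has branches of 8+ heavy atoms
        torsions = ligand_torsions(mol)
        central = max(torsions, key=lambda t: t.n_heavy_branch)
        assert central.n_heavy_branch >= 8
        cfg = MCConfig()
        max_turn = 0.0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            out = propose_move(mol.coords, [central], StepSizes(0.0, 0.0, 60.0),
                               rng, cfg)
            axis = mol.coords[central.axis_j] - mol.coords[central.axis_i]
            axis = axis / np.linalg.norm(axis)
            k = central.branch[0]
            v0 = mol.coords[k] - mol.coords[central.axis_j]
            v1 = out[k] - out[central.axis_j]
            v0p = v0 - axis * (v0 @ axis)
            v1p = v1 - axis * (v1 @ axis)
            ang = math.degrees(math.acos(np.clip(
                v0p @ v1p / (np.linalg.norm(v0p) * np.linalg.norm(v1p)), -1, 1)))
            max_turn = max(max_turn, ang)
        assert max_turn <= 60.0 * 0.15 + 1e-6


class TestMCOptimize:
    def _toy_setup(self, toy, toy_ensemble):
        from pharmdock.pose_sampler import sample_poses
        from pharmdock.pharm_rank import score_poses, rank_and_select

        poses = sample_poses(toy_ensemble, toy.sampling_model)
        score_poses(poses, toy.ligand, toy.ranking_model)
        return rank_and_select(poses, 1)[0], ReceptorPLP.from_graph(toy.receptor)

    def test_zero_steps_returns_input_with_energy(self, toy, toy_ensemble):
        pose, rec = self._toy_setup(toy, toy_ensemble)
        out = mc_optimize(pose, toy.ligand, rec, config=MCConfig(n_steps=0, seed=1))
        np.testing.assert_array_equal(out.coordinates, pose.coordinates)
        assert out.plp_energy is not None

    def test_never_worse_than_input(self, toy, toy_ensemble):
        pose, rec = self._toy_setup(toy, toy_ensemble)
        e_in = mc_optimize(pose, toy.ligand, rec, config=MCConfig(n_steps=0, seed=1)).plp_energy
        out = mc_optimize(pose, toy.ligand, rec, config=MCConfig(n_steps=300, seed=1))
        assert out.plp_energy <= e_in

    def test_trajectory_respects_leash(self, toy, toy_ensemble):
        pose, rec = self._toy_setup(toy, toy_ensemble)
        trace = []
        out = mc_optimize(pose, toy.ligand, rec,
                          config=MCConfig(n_steps=300, seed=2), trace=trace)
        assert len(trace) == 300
        cfg = MCConfig()
        for step in trace:
            assert step[4] <= cfg.rmsd_cap + 1e-9  # accepted-state RMSD to start
        heavy = toy.ligand.heavy_indices()
        assert rmsd(out.coordinates[heavy], pose.coordinates[heavy]) <= cfg.rmsd_cap

    def test_bitwise_determinism(self, toy, toy_ensemble):
        pose, rec = self._toy_setup(toy, toy_ensemble)
        t1, t2 = [], []
        o1 = mc_optimize(pose, toy.ligand, rec, config=MCConfig(n_steps=200, seed=7), trace=t1)
        o2 = mc_optimize(pose, toy.ligand, rec, config=MCConfig(n_steps=200, seed=7), trace=t2)
        np.testing.assert_array_equal(o1.coordinates, o2.coordinates)
        assert o1.plp_energy == o2.plp_energy
        assert t1 == t2

    def test_planted_minimum_retained(self, toy, toy_ensemble):
        """Starting at the engineered optimum, refinement stays nearby and
        never degrades the energy."""
        from pharmdock.pose_sampler import sample_poses

        poses = sample_poses(toy_ensemble, toy.sampling_model)
        heavy = toy.ligand.heavy_indices()
        pose = min(poses, key=lambda p: rmsd(p.coordinates[heavy],
                                             toy.planted_pose[heavy]))
        rec = ReceptorPLP.from_graph(toy.receptor)
        out = mc_optimize(pose, toy.ligand, rec, config=MCConfig(n_steps=300, seed=3))
        assert rmsd(out.coordinates[heavy], toy.planted_pose[heavy]) < 1.0
        e_in = mc_optimize(pose, toy.ligand, rec,
                           config=MCConfig(n_steps=0, seed=3)).plp_energy
        assert out.plp_energy <= e_in
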