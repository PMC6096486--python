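"""Force field, integrators, checkpoints and the settle pipeline."""
import numpy as np
import pytest

from flexfit.dynamics import (
    KB, Checkpoint, MapForces, RestraintForces, SimplifiedForceField,
    SimulationError, SimulationState, langevin_step, minimize,
    restore_checkpoint, save_checkpoint, settle_model, simplified_forcefield,
)
from flexfit.map_potential import DensityMapPotential, map_from_model
from flexfit.restraints import (
    LinearCappedRestraint, RestraintSet, add_default_omega_restraints,
    restrain_secondary_structure,
)
from flexfit.structure import Atom, Residue, StructureModel, build_ideal_peptide

from conftest import rmsd


def single_atom_model(pos=(0.0, 0.0, 0.0)):
    m = StructureModel()
    res = Residue("A", 1, "", "ALA")
    res.atoms.append(Atom("CA", "C", list(pos)))
    m.add_residue(res)
    return m


class TestSimplifiedForceField:
    def test_ideal_fixture_bonded_terms_near_zero(self, helix_mixed):
        ff = SimplifiedForceField(helix_mixed)
        pos = helix_mixed.positions()
        i, j = ff.bond_idx[:, 0], ff.bond_idx[:, 1]
        r = np.linalg.norm(pos[i] - pos[j], axis=1)
        from flexfit.dynamics import K_ANGLE, K_BOND

        assert (0.5 * K_BOND * (r - ff.bond_r0) ** 2).max() < 0.1
        i, j, k = ff.angle_idx.T
        rij, rkj = pos[i] - pos[j], pos[k] - pos[j]
        cos = (np.einsum("ij,ij->i", rij, rkj)
               / np.linalg.norm(rij, axis=1) / np.linalg.norm(rkj, axis=1))
        theta = np.arccos(np.clip(cos, -1, 1))
        assert (0.5 * K_ANGLE * (theta - ff.angle_theta0) ** 2).max() < 0.1

    def test_clash_repulsion_pushes_apart_and_is_capped(self):
        from flexfit.dynamics import NB_FORCE_CAP

        m = single_atom_model()
        res = Residue("B", 1, "", "ALA")
        res.atoms.append(Atom("CA", "C", [0.5, 0.0, 0.0]))
        m.add_residue(res)
        ff = SimplifiedForceField(m)
        _, f = ff.evaluate(m.positions())
        assert f[0, 0] < 0 < f[1, 0]
        assert np.linalg.norm(f[0]) <= NB_FORCE_CAP + 1e-9

    def test_forces_match_finite_differences(self, helix_mixed):
        ff = SimplifiedForceField(helix_mixed)
        rng = np.random.default_rng(0)
        pos = helix_mixed.positions() + rng.normal(
            size=(helix_mixed.n_atoms, 3)) * 0.05
        e0, f0 = ff.evaluate(pos)
        h = 1e-5
        for _ in range(60):
            i = int(rng.integers(len(pos)))
            j = int(rng.integers(3))
            pp, pm = pos.copy(), pos.copy()
            pp[i, j] += h
            pm[i, j] -= h
            fd = -(ff.evaluate(pp)[0] - ff.evaluate(pm)[0]) / (2 * h)
            assert fd == pytest.approx(f0[i, j], rel=1e-5, abs=1e-4)

    def test_unknown_residue_raises_naming_it(self):
        m = StructureModel()
        res = Residue("A", 1, "", "!!X")
        res.atoms.append(Atom("C1", "C", [0, 0, 0]))
        res.atoms.append(Atom("C2", "C", [1.5, 0, 0]))
        m.add_residue(res)
        with pytest.raises(SimulationError) as err:
            simplified_forcefield(m)
        assert "!!X" in str(err.value)


class TestAdditivity:
    def test_total_is_sum_over_providers(self, helix20):
        rset = RestraintSet()
        add_default_omega_restraints(rset, helix20)
        restrain_secondary_structure(
            rset, helix20, [("A", i, "") for i in range(4, 12)], "helix")
        dm = map_from_model(helix20, 0.8, voxel=0.6, padding=3.0)
        state = SimulationState(helix20.copy(), restraints=rset)
        state.use_default_providers(DensityMapPotential(dm, weight=5.0))
        rng = np.random.default_rng(1)
        pos = state.positions + rng.normal(size=state.positions.shape) * 0.1
        total, _ = state.compute(pos)
        parts = state.energy_breakdown(pos)
        assert total == pytest.approx(sum(parts.values()), rel=1e-12)
        assert set(parts) == {"forcefield", "restraints", "map"}

    def test_restraint_forces_match_standalone_evaluation(self, helix20):
        rset = RestraintSet()
        add_default_omega_restraints(rset, helix20)
        state = SimulationState(helix20.copy(), restraints=rset)
        provider = RestraintForces(state)
        pos = state.positions
        e, _ = provider.evaluate(pos)
        idx = helix20.atom_index()
        manual = 0.0
        for r in rset.dihedrals.values():
            quad = np.array([pos[idx[tuple(a)]] for a in r.atoms])
            manual += r.energy_forces(quad)[0]
        assert e == pytest.approx(manual, abs=1e-12)


class TestMinimize:
    def test_already_minimal_returns_immediately(self, helix20):
        rset = RestraintSet()
        state = SimulationState(helix20.copy(), restraints=rset)
        state.add_provider(RestraintForces(state))  # zero-energy landscape
        before = state.positions.copy()
        minimize(state, max_steps=100, force_tol=10.0)
        assert len(state.minimization_trace) == 1
        assert np.abs(state.positions - before).max() < 1e-4

    def test_displaced_atom_restored_by_position_restraint(self, helix20):
        m = helix20.copy()
        target = m.residue(("A", 10, "")).atom("CA").position.copy()
        rset = RestraintSet()
        rset.add_position(LinearCappedRestraint(
            kind="position", atoms=(("A", 10, "", "CA"),), target=target,
            k=500.0, f_max=100.0))
        state = SimulationState(m, restraints=rset)
        state.add_provider(RestraintForces(state))
        i = m.atom_index()[("A", 10, "", "CA")]
        state.positions[i] += np.array([0.5, 0.0, 0.0])
        minimize(state, max_steps=200, force_tol=0.5)
        assert np.abs(state.positions[i] - target).max() < 0.05

    def test_energy_trace_monotone_nonincreasing(self, helix20):
        m = helix20.copy()
        rng = np.random.default_rng(2)
        state = SimulationState(m)
        state.use_default_providers()
        state.positions += rng.normal(size=state.positions.shape) * 0.15
        minimize(state, max_steps=150, force_tol=1.0)
        trace = state.minimization_trace
        assert len(trace) > 2
        assert all(b <= a + 1e-6 for a, b in zip(trace, trace[1:]))

    def test_fixed_atoms_never_move(self, helix20):
        m = helix20.copy()
        rng = np.random.default_rng(3)
        mobile_keys = [("A", i, "") for i in range(5, 16)]
        state = SimulationState(m, mobile_keys=mobile_keys)
        state.use_default_providers()
        state.positions += (rng.normal(size=state.positions.shape) * 0.1
                            * state.mobile[:, None])
        fixed_before = state.positions[~state.mobile].copy()
        minimize(state, max_steps=100, force_tol=5.0)
        langevin_step(state, 100)
        assert np.array_equal(state.positions[~state.mobile], fixed_before)


class TestLangevin:
    def test_zero_temperature_energy_nonincreasing(self, helix20):
        m = helix20.copy()
        rng = np.random.default_rng(4)
        state = SimulationState(m, temperature=0.0, seed=5)
        state.use_default_providers()
        state.validation_cadence = 0
        state.positions += rng.normal(size=state.positions.shape) * 0.08
        energies = [state.compute()[0] + state.kinetic_energy()]
        for _ in range(10):
            langevin_step(state, 20)  # one coordinate update at a time
            energies.append(state.compute()[0] + state.kinetic_energy())
        assert all(b <= a + 1e-6 for a, b in zip(energies, energies[1:]))

    def test_equipartition_of_restrained_atom(self):
        # positional variance of a harmonically restrained atom at 100 K
        # must satisfy var = kB T / k per axis
        k = 10.0
        m = single_atom_model()
        rset = RestraintSet()
        rset.add_position(LinearCappedRestraint(
            kind="position", atoms=(("A", 1, "", "CA"),),
            target=[0.0, 0.0, 0.0], k=k, f_max=1000.0))
        state = SimulationState(m, restraints=rset, temperature=100.0, seed=8)
        state.add_provider(RestraintForces(state))
        state.validation_cadence = 0
        langevin_step(state, 5000)  # equilibrate
        samples = []
        for _ in range(400):
            langevin_step(state, 200)
            samples.append(state.positions[0].copy())
        var = np.array(samples).var(axis=0).mean()
        assert var == pytest.approx(KB * 100.0 / k, rel=0.2)

    def test_determinism_with_same_seed(self, helix20):
        def trajectory(seed):
            state = SimulationState(helix20.copy(), temperature=100.0,
                                    seed=seed)
            state.use_default_providers()
            state.validation_cadence = 0
            langevin_step(state, 60)
            return state.positions

        assert np.array_equal(trajectory(3), trajectory(3))
        assert not np.array_equal(trajectory(3), trajectory(4))

    def test_unstable_step_aborts_with_diagnostic(self):
        m = single_atom_model()
        rset = RestraintSet()
        rset.add_position(LinearCappedRestraint(
            kind="position", atoms=(("A", 1, "", "CA"),),
            target=[500.0, 0.0, 0.0], k=1e6, f_max=1e9))
        state = SimulationState(m, restraints=rset, temperature=0.0)
        state.add_provider(RestraintForces(state))
        with pytest.raises(SimulationError):
            langevin_step(state, 50)


class TestCheckpoints:
    def test_save_perturb_restore_bit_identical(self, helix20):
        state = SimulationState(helix20.copy(), seed=0)
        state.use_default_providers()
        cp = save_checkpoint(state)
        rng = np.random.default_rng(0)
        state.positions += rng.normal(size=state.positions.shape)
        restore_checkpoint(state, cp)
        assert np.array_equal(state.positions, cp.positions)
        assert state.positions is not cp.positions

    def test_restraint_set_restored_exactly(self, helix20):
        rset = RestraintSet()
        add_default_omega_restraints(rset, helix20)
        state = SimulationState(helix20.copy(), restraints=rset)
        state.use_default_providers()
        cp = save_checkpoint(state)
        n0 = len(state.restraints)
        restrain_secondary_structure(
            state.restraints, state.model,
            [("A", i, "") for i in range(4, 12)], "helix")
        assert len(state.restraints) > n0
        restore_checkpoint(state, cp)
        assert len(state.restraints) == n0
        assert set(state.restraints.dihedrals) == set(cp.restraints.dihedrals)

    def test_multiple_checkpoints_coexist(self, helix20):
        state = SimulationState(helix20.copy(), temperature=50.0, seed=1)
        state.use_default_providers()
        state.validation_cadence = 0
        cp1 = save_checkpoint(state)
        langevin_step(state, 40)
        cp2 = save_checkpoint(state)
        langevin_step(state, 40)
        restore_checkpoint(state, cp1)
        assert np.array_equal(state.positions, cp1.positions)
        restore_checkpoint(state, cp2)
        assert np.array_equal(state.positions, cp2.positions)

    def test_wrong_topology_rejected(self, helix20, helix_mixed):
        s1 = SimulationState(helix20.copy())
        s2 = SimulationState(helix_mixed.copy())
        cp = save_checkpoint(s1)
        with pytest.raises(SimulationError):
            restore_checkpoint(s2, cp)

    def test_disk_round_trip(self, helix20, tmp_path):
        rset = RestraintSet()
        add_default_omega_restraints(rset, helix20)
        state = SimulationState(helix20.copy(), restraints=rset)
        cp = save_checkpoint(state)
        p = tmp_path / "cp.json"
        p.write_text(cp.to_json())
        again = Checkpoint.from_json(p.read_text())
        assert np.array_equal(again.positions, cp.positions)
        assert len(again.restraints) == len(cp.restraints)


class TestSettleModel:
    def test_recovers_jittered_helix_against_map(self, helix20):
        rng = np.random.default_rng(11)
        truth = helix20.positions()
        jittered = helix20.copy()
        jittered.set_positions(truth + rng.normal(size=truth.shape) * 0.3)
        dm = map_from_model(helix20, resolution_sigma=0.75, voxel=0.5,
                            padding=4.0)
        out, report = settle_model(jittered, density_map=dm, map_weight=20.0,
                                   md_steps=400, seed=3, validate=False)
        assert rmsd(out.positions(), truth) < 0.2

    def test_no_map_no_noise_energy_drops(self, helix_mixed):
        out, report = settle_model(helix_mixed, temperature=0.0, md_steps=100,
                                   seed=0, validate=False)
        assert report["energy_final"] <= report["energy_initial"]

    def test_clash_resolved(self, helix20):
        # push two residues' CB atoms to 0.8 A apart, settle, and verify
        # the closest nonbonded heavy pair ends well separated
        m = build_ideal_peptide("AAAA", "alpha")
        other = build_ideal_peptide("AAAA", "alpha", chain_id="B")
        cb_a = m.residue(("A", 2, "")).atom("CB").position
        cb_b = other.residue(("B", 2, "")).atom("CB").position
        shift = cb_a + np.array([0.8, 0.0, 0.0]) - cb_b
        for r in other.residues():
            for a in r.atoms:
                a.position = a.position + shift
        for r in other.residues():
            m.add_residue(r)
        ff = SimplifiedForceField(m)
        assert ff.min_nonbonded_distance(m.positions()) < 1.0
        out, _ = settle_model(m, temperature=50.0, md_steps=300, seed=2,
                              validate=False)
        assert ff.min_nonbonded_distance(out.positions()) > 2.0

    def test_input_model_untouched(self, helix20):
        before = helix20.positions().copy()
        settle_model(helix20, temperature=50.0, md_steps=60, seed=0,
                     validate=False)
        assert np.array_equal(helix20.positions(), before)

    def test_validation_log_refreshes_every_ten_frames(self, helix20):
        state = SimulationState(helix20.copy(), temperature=50.0, seed=0)
        state.use_default_providers()
        langevin_step(state, 20 * 25)   # 25 coordinate updates
        frames = [e["frame"] for e in state.validation_log]
        assert frames == [10, 20]
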