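"""Restraint force laws, lifecycle and scripted operations."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flexfit.restraints import (
    CUTOFF_BACKBONE, CUTOFF_CHI, DihedralRestraint, LinearCappedRestraint,
    RestraintError, RestraintSet, add_default_omega_restraints,
    apply_rotamer_target, dihedral_and_gradient, dihedral_restraint_energy,
    flip_cis_trans, flip_peptide_plane, linear_capped_energy,
    linear_capped_force, restrain_secondary_structure, tug,
)
from flexfit.structure import build_ideal_peptide, measure_dihedral

QUAD = (("A", 1, "", "CA"), ("A", 1, "", "C"), ("A", 2, "", "N"),
        ("A", 2, "", "CA"))
BASE = np.array([[0.0, 1.0, 0.3], [0.0, 0.0, 0.0],
                 [1.5, 0.0, 0.0], [2.0, -1.2, 0.4]])


def random_quad(rng, spread=0.35):
    return BASE + rng.normal(size=(4, 3)) * spread


# ---------------------------------------------------------------------------
# flat-bottomed dihedral restraint
# ---------------------------------------------------------------------------

class TestDihedralRestraint:
    def test_zero_inside_flat_bottom(self):
        r = DihedralRestraint(atoms=QUAD, kind="omega", target=180.0,
                              k=100.0, cutoff=30.0)
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = random_quad(rng)
            theta = measure_dihedral(*p)
            e, f = r.energy_forces(p)
            if abs(r.delta(theta)) <= 30.0:
                assert e == 0.0 and np.all(f == 0.0)

    def test_boundary_continuity(self):
        r = DihedralRestraint(atoms=QUAD, kind="phi", target=0.0, k=50.0,
                              cutoff=30.0)
        # energy just outside the cutoff tends to zero at the boundary
        for eps in (1e-3, 1e-5):
            dtheta = math.radians(30.0 + eps)
            e = 50.0 * (math.cos(math.radians(30.0)) - math.cos(dtheta))
            assert 0.0 < e < 1e-3

    def test_closed_form_value(self):
        # k = 10, cutoff 30 deg, delta 60 deg
        e = 10.0 * (math.cos(math.radians(30)) - math.cos(math.radians(60)))
        assert e == pytest.approx(3.6603, abs=1e-4)
        r = DihedralRestraint(atoms=QUAD, kind="phi", target=0.0, k=10.0,
                              cutoff=30.0)
        # build a quadruple with dihedral exactly 60 deg
        p = np.array([[0, 1, 0], [0, 0, 0], [1.5, 0, 0], [1.5, 0, 0]],
                     dtype=float)
        ang = math.radians(60.0)
        p[3] = p[2] + np.array([0.0, math.cos(ang), math.sin(ang)])
        assert measure_dihedral(*p) == pytest.approx(60.0, abs=1e-9)
        e_r, _ = r.energy_forces(p)
        assert e_r == pytest.approx(3.6603, abs=1e-4)

    def test_metastable_at_180(self):
        # dE/dtheta = k sin(delta) vanishes at delta = 180 while E is maximal
        r = DihedralRestraint(atoms=QUAD, kind="omega", target=0.0, k=25.0,
                              cutoff=30.0)
        p = np.array([[0, 1, 0], [0, 0, 0], [1.5, 0, 0], [1.5, -1, 0]],
                     dtype=float)
        assert abs(measure_dihedral(*p)) == pytest.approx(180.0, abs=1e-9)
        e, f = r.energy_forces(p)
        assert e == pytest.approx(
            25.0 * (math.cos(math.radians(30)) + 1.0), abs=1e-9)
        assert np.abs(f).max() < 1e-9

    def test_periodicity(self):
        r = DihedralRestraint(atoms=QUAD, kind="phi", target=10.0, k=30.0,
                              cutoff=20.0)
        for d in (-170.0, 45.0, 120.0):
            e1 = 30.0 * (math.cos(math.radians(20)) - math.cos(math.radians(d)))
            e2 = 30.0 * (math.cos(math.radians(20))
                         - math.cos(math.radians(d + 360.0)))
            assert e1 == pytest.approx(e2, abs=1e-12)

    def test_forces_match_finite_differences(self):
        r = DihedralRestraint(atoms=QUAD, kind="phi", target=0.0, k=120.0,
                              cutoff=30.0)
        rng = np.random.default_rng(3)
        checked = 0
        while checked < 1000:
            p = random_quad(rng)
            delta = abs(r.delta(measure_dihedral(*p)))
            if delta < 32.0 or delta > 178.0:  # skip boundary neighbourhoods
                continue
            e, f = r.energy_forces(p)
            checked += 1
            h = 1e-5
            for i in range(4):
                for j in range(3):
                    pp, pm = p.copy(), p.copy()
                    pp[i, j] += h
                    pm[i, j] -= h
                    fd = -(r.energy_forces(pp)[0]
                           - r.energy_forces(pm)[0]) / (2 * h)
                    assert fd == pytest.approx(f[i, j],
                                               rel=1e-5, abs=1e-6)

    def test_invalid_parameters_raise(self):
        with pytest.raises(RestraintError):
            DihedralRestraint(atoms=QUAD, kind="phi", target=0, cutoff=180.0)
        with pytest.raises(RestraintError):
            DihedralRestraint(atoms=QUAD, kind="phi", target=0, k=-1.0)

    def test_functional_wrapper(self):
        r = DihedralRestraint(atoms=QUAD, kind="phi", target=0.0, k=10.0)
        p = random_quad(np.random.default_rng(1))
        assert dihedral_restraint_energy(r, p)[0] == r.energy_forces(p)[0]


# ---------------------------------------------------------------------------
# linear-capped restraint
# ---------------------------------------------------------------------------

class TestLinearCapped:
    def test_examples(self):
        assert linear_capped_force(3.0, 3.0, 500.0, 100.0) == 0.0
        assert linear_capped_force(3.05, 3.0, 500.0, 100.0) == \
            pytest.approx(25.0)
        assert linear_capped_force(4.0, 3.0, 500.0, 100.0) == 100.0

    def test_negative_inputs_raise(self):
        with pytest.raises(RestraintError):
            linear_capped_force(-1.0, 0.0, 500.0, 100.0)
        with pytest.raises(RestraintError):
            linear_capped_energy(1.0, 0.0, 500.0, -5.0)

    @settings(deadline=None, max_examples=300)
    @given(st.floats(0, 50), st.floats(0, 10),
           st.floats(1, 2000), st.floats(0.1, 500))
    def test_force_never_exceeds_cap(self, r, r0, k, fmax):
        assert linear_capped_force(r, r0, k, fmax) <= fmax + 1e-12

    def test_energy_is_c1_integral(self):
        k, fmax, r0 = 500.0, 100.0, 3.0
        rc = r0 + fmax / k
        # continuity of E and dE/dr at the crossover
        h = 1e-7
        e_below = linear_capped_energy(rc - h, r0, k, fmax)
        e_above = linear_capped_energy(rc + h, r0, k, fmax)
        assert e_above - e_below == pytest.approx(2 * h * fmax, rel=1e-3)
        # force = dE/dr everywhere off the kink
        rng = np.random.default_rng(0)
        for _ in range(300):
            r = float(rng.uniform(0, 8))
            if abs(r - rc) < 1e-3 or abs(r - r0) < 1e-3:
                continue
            fd = (linear_capped_energy(r + h, r0, k, fmax)
                  - linear_capped_energy(r - h, r0, k, fmax)) / (2 * h)
            assert abs(fd) == pytest.approx(
                linear_capped_force(r, r0, k, fmax), rel=1e-5, abs=1e-6)

    def test_restraint_object_validation(self):
        with pytest.raises(RestraintError):
            LinearCappedRestraint(kind="spring", atoms=(QUAD[0],))
        with pytest.raises(RestraintError):
            LinearCappedRestraint(kind="position", atoms=(QUAD[0],),
                                  target=None)
        with pytest.raises(RestraintError):
            LinearCappedRestraint(kind="distance", atoms=(QUAD[0],))


# ---------------------------------------------------------------------------
# default omega restraints and flips
# ---------------------------------------------------------------------------

class TestOmegaLifecycle:
    def test_only_omegas_restrained_on_load(self, helix20):
        rset = RestraintSet()
        n = add_default_omega_restraints(rset, helix20)
        assert n == 19
        assert len(rset.dihedrals) == 19
        assert all(k[1] == "omega" for k in rset.dihedrals)
        assert len(rset.distances) == len(rset.positions) == 0

    def test_targets_nearer_planar_state(self, helix20):
        rset = RestraintSet()
        add_default_omega_restraints(rset, helix20)
        assert all(r.target == 180.0 for r in rset.dihedrals.values())
        assert all(r.cutoff == CUTOFF_BACKBONE
                   for r in rset.dihedrals.values())

    def test_flip_cis_trans_toggles_to_farther_state(self, helix20):
        rset = RestraintSet()
        add_default_omega_restraints(rset, helix20)
        r = flip_cis_trans(rset, helix20, ("A", 5, ""))
        assert r.target == 0.0
        r = flip_cis_trans(rset, helix20, ("A", 5, ""))
        assert r.target == 180.0  # involution

    def test_flip_without_omega_raises(self, helix20):
        rset = RestraintSet()
        with pytest.raises(RestraintError):
            flip_cis_trans(rset, helix20, ("A", 1, ""))

    def test_flip_peptide_plane_targets(self, helix20):
        rset = RestraintSet()
        made = flip_peptide_plane(rset, helix20, ("A", 5, ""))
        targets = sorted(round(r.target, 1) for r in made)
        # psi(-47)+180 = 133, phi(-57)+180 = 123
        assert targets == [123.0, 133.0]
        assert all(r.temporary for r in made)

    def test_flip_peptide_auto_release_when_satisfied(self, helix20):
        m = helix20.copy()
        rset = RestraintSet()
        baseline = len(rset)
        made = flip_peptide_plane(rset, m, ("A", 5, ""), frame=0)
        assert len(rset) == baseline + 2
        # fake satisfaction: move targets onto the current angles
        for r in made:
            r.target = r.target - 180.0
        rset.check_temporaries(m, frame=1)
        assert len(rset) == baseline

    def test_flip_peptide_budget_expiry_warns(self, helix20, caplog):
        m = helix20.copy()
        rset = RestraintSet()
        flip_peptide_plane(rset, m, ("A", 5, ""), frame=0, budget=10)
        import logging

        with caplog.at_level(logging.WARNING, logger="flexfit"):
            rset.check_temporaries(m, frame=10)
        assert len(rset) == 0
        assert any("not met" in rec.message for rec in caplog.records)


# ---------------------------------------------------------------------------
# bundles: secondary structure, rotamers, tugging
# ---------------------------------------------------------------------------

class TestBundles:
    def test_helix_bundle_counts(self, helix20):
        rset = RestraintSet()
        sel = [("A", i, "") for i in range(6, 16)]  # interior 10-residue run
        bundle = restrain_secondary_structure(rset, helix20, sel, "helix")
        assert len(rset.dihedrals) == 20   # 10 phi + 10 psi
        o_n = [r for r in rset.distances.values()
               if {a[3] for a in r.atoms} == {"O", "N"}]
        ca_ca = [r for r in rset.distances.values()
                 if {a[3] for a in r.atoms} == {"CA"}]
        assert len(o_n) == 6 and len(ca_ca) == 8
        n = rset.release_bundle(bundle)
        assert n == 34 and len(rset) == 0

    def test_three_residue_helix_counts(self, helix20):
        rset = RestraintSet()
        sel = [("A", i, "") for i in range(8, 11)]
        restrain_secondary_structure(rset, helix20, sel, "helix")
        ca_ca = [r for r in rset.distances.values()
                 if {a[3] for a in r.atoms} == {"CA"}]
        o_n = [r for r in rset.distances.values()
               if {a[3] for a in r.atoms} == {"O", "N"}]
        assert len(ca_ca) == 1 and len(o_n) == 0

    def test_strand_has_no_o_n_restraints(self, helix20):
        rset = RestraintSet()
        sel = [("A", i, "") for i in range(5, 12)]
        restrain_secondary_structure(rset, helix20, sel, "strand")
        assert all({a[3] for a in r.atoms} == {"CA"}
                   for r in rset.distances.values())

    def test_non_contiguous_selection_raises(self, helix20):
        rset = RestraintSet()
        with pytest.raises(RestraintError):
            restrain_secondary_structure(
                rset, helix20,
                [("A", 1, ""), ("A", 2, ""), ("A", 9, "")], "helix")

    def test_rotamer_targets(self):
        m = build_ideal_peptide("LSA", "alpha")
        rset = RestraintSet()
        made = apply_rotamer_target(rset, m, ("A", 1, ""), (-60.0, 180.0))
        assert [r.kind for r in made] == ["chi1", "chi2"]
        assert all(r.cutoff == CUTOFF_CHI for r in made)
        made = apply_rotamer_target(rset, m, ("A", 2, ""), (64.0,))
        assert len(made) == 1
        # re-application replaces, not duplicates
        apply_rotamer_target(rset, m, ("A", 1, ""), (55.0, 60.0))
        chi1 = rset.dihedrals[(("A", 1, ""), "chi1")]
        assert chi1.target == 55.0
        assert len(rset.dihedrals) == 3

    def test_rotamer_on_alanine_raises(self):
        m = build_ideal_peptide("A", "alpha")
        with pytest.raises(RestraintError):
            apply_rotamer_target(RestraintSet(), m, ("A", 1, ""), (0.0,))

    def test_tug_zero_force_at_target(self, helix20):
        rset = RestraintSet()
        atom_key = ("A", 10, "", "CA")
        pos = helix20.residue(("A", 10, "")).atom("CA").position
        r = tug(rset, helix20, atom_key, pos)
        e, f = r.energy_force_scalar(0.0)
        assert e == 0.0 and f == 0.0

    def test_tug_cap_engaged_far_away(self, helix20):
        rset = RestraintSet()
        atom_key = ("A", 10, "", "CA")
        pos = helix20.residue(("A", 10, "")).atom("CA").position
        r = tug(rset, helix20, atom_key, pos + np.array([10.0, 0, 0]),
                k=500.0, f_max=40.0)
        _, f = r.energy_force_scalar(10.0)
        assert f == 40.0

    def test_one_tug_per_atom(self, helix20):
        rset = RestraintSet()
        atom_key = ("A", 10, "", "CA")
        tug(rset, helix20, atom_key, (0, 0, 0))
        r2 = tug(rset, helix20, atom_key, (5, 5, 5))
        tugs = [r for (k, kind), r in rset.positions.items() if kind == "tug"]
        assert len(tugs) == 1 and np.all(tugs[0].target == (5, 5, 5))
        assert tugs[0] is r2


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def test_restraint_set_json_round_trip(helix20):
    rset = RestraintSet()
    add_default_omega_restraints(rset, helix20)
    restrain_secondary_structure(
        rset, helix20, [("A", i, "") for i in range(5, 12)], "helix")
    tug(rset, helix20, ("A", 3, "", "CA"), (1.0, 2.0, 3.0))
    again = RestraintSet.from_json(rset.to_json())
    assert len(again) == len(rset)
    assert set(again.dihedrals) == set(rset.dihedrals)
    for key, r in rset.dihedrals.items():
        assert again.dihedrals[key].target == r.target
        assert again.dihedrals[key].k == r.k
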