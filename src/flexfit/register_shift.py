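"""Register-shift correction via backbone splines and moving restraints.

A register error is a stretch of sequence modelled one or more positions
out of step with the density.  The fix: fit parametric cubic splines to
the N, C, CA and (where present) CB positions as functions of residue
position along the run, then tug each residue's backbone atoms smoothly
along the splines until residue i occupies the original site of residue
i+n (negative n shifts toward the N-terminus).  Targets advance at every
coordinate update (20 simulation timesteps), traversing one register unit
every ten updates, and the position restraints persist at their final
targets until explicitly released so side chains can be inspected first.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline, make_interp_spline

from .restraints import (
    DEFAULT_DISTANCE_K, DEFAULT_F_MAX, LinearCappedRestraint, RestraintError,
)
from .structure import FlexfitError, Residue, StructureModel, residues_bonded

log = logging.getLogger("flexfit")

SPLINE_ATOMS = ("N", "C", "CA", "CB")
UPDATES_PER_REGISTER = 10
TIMESTEPS_PER_UPDATE = 20


class RegisterShiftError(FlexfitError):
    pass


@dataclass
class BackboneSplines:
    """Parametric splines t -> position for N, C, CA and CB.

    ``t`` is the continuous residue index (0-based ordinal within the
    fitted run).  The CB spline interpolates through the residues that
    have a CB (glycines contribute no control point) and is flagged
    absent when fewer than two residues do.
    """
    splines: dict[str, object]
    t_range: dict[str, tuple[float, float]]

    def has(self, atom_name: str) -> bool:
        return atom_name in self.splines

    def evaluate(self, atom_name: str, t: float, clamp: bool = True) -> np.ndarray:
        sp = self.splines[atom_name]
        lo, hi = self.t_range[atom_name]
        if clamp:
            t = min(max(t, lo), hi)
        return np.asarray(sp(t), dtype=float)


def fit_backbone_splines(model: StructureModel, selection) -> BackboneSplines:
    """Interpolating natural cubic splines through the run's backbone atoms.

    ``selection`` is an ordered, contiguous residue run (keys or Residue
    objects) of length >= 4 in one chain.  A missing N/C/CA raises an
    error naming the residue.
    """
    run = [r if isinstance(r, Residue) else model.residue(r) for r in selection]
    if len(run) < 4:
        raise RegisterShiftError("spline fitting needs a run of >= 4 residues")
    chain_id = run[0].chain_id
    chain = model.chains[chain_id]
    idx = [chain.index(r) for r in run]
    if any(r.chain_id != chain_id for r in run) or \
            idx != list(range(idx[0], idx[0] + len(run))):
        raise RegisterShiftError("selection is not contiguous in one chain")
    for r1, r2 in zip(run, run[1:]):
        if not residues_bonded(r1, r2):
            raise RegisterShiftError(
                f"chain break between {r1.key} and {r2.key}")

    splines, t_range = {}, {}
    for name in SPLINE_ATOMS:
        ts, pts = [], []
        for i, res in enumerate(run):
            atom = res.atom(name)
            if atom is None:
                if name == "CB":
                    continue  # glycine (or stub): no control point
                raise RegisterShiftError(
                    f"residue {res.key} is missing backbone atom {name}")
            ts.append(float(i))
            pts.append(atom.position)
        if len(ts) < 2:
            continue  # CB spline absent
        ts, pts = np.array(ts), np.array(pts)
        if len(ts) >= 4:
            sp = CubicSpline(ts, pts, bc_type="natural")
        else:
            sp = make_interp_spline(ts, pts, k=len(ts) - 1)
        splines[name] = sp
        t_range[name] = (float(ts[0]), float(ts[-1]))
    return BackboneSplines(splines=splines, t_range=t_range)


@dataclass
class RegisterShiftPlan:
    """A planned register shift of a contiguous run by ``shift`` units."""
    selection: list[tuple]            # ordered residue keys
    shift: int
    splines: BackboneSplines | None = None
    updates_per_register: int = UPDATES_PER_REGISTER
    timesteps_per_update: int = TIMESTEPS_PER_UPDATE
    progress: float = 0.0
    released: bool = False
    end_handling: str = "clamp"       # clamp | extrapolate
    bundle_id: str | None = field(default=None, repr=False)

    def __post_init__(self):
        if abs(int(self.shift)) < 1:
            raise RegisterShiftError("shift must be a nonzero integer")
        self.shift = int(self.shift)
        self.selection = [tuple(k) for k in self.selection]

    @property
    def total_updates(self) -> int:
        return self.updates_per_register * abs(self.shift)

    def fit(self, model: StructureModel) -> "RegisterShiftPlan":
        self.splines = fit_backbone_splines(model, self.selection)
        return self

    def grow(self, model: StructureModel, n_start: int = 0, n_end: int = 0):
        """Edit the selection before fitting: positive grows, negative shrinks."""
        if self.splines is not None:
            raise RegisterShiftError("cannot edit a plan after fitting")
        chain = model.chains[self.selection[0][0]]
        keys = [r.key for r in chain]
        i0 = keys.index(self.selection[0]) - n_start
        i1 = keys.index(self.selection[-1]) + n_end
        if i0 < 0 or i1 >= len(keys) or i1 - i0 + 1 < 4:
            raise RegisterShiftError("grown/shrunk selection out of range")
        self.selection = keys[i0:i1 + 1]

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        doc = {"selection": [list(k) for k in self.selection],
               "shift": self.shift,
               "updates_per_register": self.updates_per_register,
               "timesteps_per_update": self.timesteps_per_update,
               "end_handling": self.end_handling,
               "progress": self.progress}
        if self.splines is not None:
            doc["spline_knots"] = {
                name: {"t": np.asarray(sp.x if hasattr(sp, "x") else sp.t).tolist(),
                       "range": list(self.splines.t_range[name])}
                for name, sp in self.splines.splines.items()}
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RegisterShiftPlan":
        doc = json.loads(text)
        return cls(selection=[tuple(k) for k in doc["selection"]],
                   shift=doc["shift"],
                   updates_per_register=doc["updates_per_register"],
                   timesteps_per_update=doc["timesteps_per_update"],
                   end_handling=doc.get("end_handling", "clamp"),
                   progress=doc.get("progress", 0.0))


def shift_targets(plan: RegisterShiftPlan, progress: float
                  ) -> dict[tuple, np.ndarray]:
    """Target positions for the N/C/CA/CB atoms at a given progress.

    The target of residue ordinal i, atom a, is spline_a(i + progress *
    shift); indices beyond the fitted range clamp to the run ends (or
    linearly extrapolate if the plan says so).  At progress 1 every
    interior residue targets the original position of residue i + shift.
    """
    if plan.splines is None:
        raise RegisterShiftError("plan is not fitted")
    if not 0.0 <= progress <= 1.0:
        raise RegisterShiftError("progress must be in [0, 1]")
    clamp = plan.end_handling == "clamp"
    targets = {}
    for i, key in enumerate(plan.selection):
        t = i + progress * plan.shift
        for name in SPLINE_ATOMS:
            if not plan.splines.has(name):
                continue
            targets[key + (name,)] = plan.splines.evaluate(name, t, clamp=clamp)
    return targets


def execute_register_shift(state, plan: RegisterShiftPlan,
                           k: float = DEFAULT_DISTANCE_K,
                           f_max: float = DEFAULT_F_MAX,
                           settle_updates: int = 5):
    """Run a fitted plan inside a simulation.

    Removes every pre-existing restraint on the selected residues, attaches
    moving position restraints to the run's N/C/CA/CB atoms and advances
    them one register unit per ten coordinate updates.  On completion the
    restraints stay at their final targets until :func:`release_plan`.
    Returns the updated simulation state.
    """
    if plan.splines is None:
        plan.fit(state.model)
    mobile_keys = state.mobile_residue_keys()
    outside = [k_ for k_ in plan.selection if k_ not in mobile_keys]
    if outside:
        raise RegisterShiftError(
            f"{len(outside)} selected residue(s) outside the mobile set")
    removed = state.restraints.remove_for_residues(plan.selection)
    if removed:
        log.info("register shift removed %d pre-existing restraint(s)", removed)

    idx = state.model.atom_index()
    bundle = state.restraints.new_bundle("register-shift")
    _add_omega_keepers(state, plan, bundle)
    restraint_for: dict[tuple, LinearCappedRestraint] = {}
    for atom_key, target in shift_targets(plan, 0.0).items():
        if atom_key not in idx:
            continue  # e.g. CB target for a residue without CB
        r = LinearCappedRestraint(kind="position", atoms=(atom_key,),
                                  target=target, k=k, f_max=f_max)
        state.restraints.add_position(r, bundle=bundle)
        restraint_for[atom_key] = r
    plan.bundle_id = bundle
    plan.progress = 0.0

    def advance(_state):
        if plan.progress >= 1.0:
            return
        plan.progress = min(1.0, plan.progress + 1.0 / plan.total_updates)
        for atom_key, target in shift_targets(plan, plan.progress).items():
            if atom_key in restraint_for:
                restraint_for[atom_key].target = target
        _state.restraints._touch()

    state.moving_updaters.append(advance)
    n_steps = (plan.total_updates + settle_updates) * plan.timesteps_per_update
    state.run(n_steps)
    state.moving_updaters.remove(advance)
    return state


def _add_omega_keepers(state, plan: RegisterShiftPlan, bundle: str) -> None:
    """Restrain the run's peptide bonds (and the two boundary bonds) to
    their planar state while the backbone is transported.

    The maintenance force field treats cis and trans symmetrically, so
    without these a peptide under large transport forces can flip and
    become trapped; they are part of the plan's bundle and disappear on
    release.
    """
    from .restraints import (
        CUTOFF_BACKBONE, DEFAULT_DIHEDRAL_K, DihedralRestraint,
    )
    from .structure import DihedralError, measure_dihedral

    model = state.model
    chain = [r for r in model.chains[plan.selection[0][0]] if r.is_amino_acid]
    keys = [r.key for r in chain]
    i0 = keys.index(plan.selection[0])
    i1 = keys.index(plan.selection[-1])
    idx = model.atom_index()
    flat = model.atom_list()
    for i in range(max(1, i0), min(len(chain), i1 + 2)):
        prev, res = chain[i - 1], chain[i]
        if (res.key, "omega") in state.restraints.dihedrals:
            continue  # an active restraint (e.g. the default) already holds it
        quad = (prev.key + ("CA",), prev.key + ("C",),
                res.key + ("N",), res.key + ("CA",))
        if not all(k in idx for k in quad):
            continue
        # trans unless this is a genuine (measurable) cis-proline: across
        # the distorted boundary bonds of a register error the current
        # angle is meaningless, and cis-nonproline is essentially always
        # an error
        target = 180.0
        if res.name == "PRO":
            try:
                omega = measure_dihedral(
                    *(flat[idx[k]][1].position for k in quad))
                if abs(omega) < 90.0:
                    target = 0.0
            except DihedralError:
                pass
        state.restraints.add_dihedral(
            res.key, DihedralRestraint(atoms=quad, kind="omega",
                                       target=target, k=DEFAULT_DIHEDRAL_K,
                                       cutoff=CUTOFF_BACKBONE),
            bundle=bundle)


def release_plan(state, plan: RegisterShiftPlan) -> int:
    """Dismiss the plan's position restraints; returns the number removed."""
    if plan.bundle_id is None:
        raise RegisterShiftError("plan has no active restraints")
    n = state.restraints.release_bundle(plan.bundle_id)
    plan.bundle_id = None
    plan.released = True
    return n
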