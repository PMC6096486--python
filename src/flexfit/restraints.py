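"""Interactive-rebuilding restraints: energies, forces and lifecycle.

Two force laws cover everything:

* flat-bottomed cosine dihedral restraint
      E = 0                                  for |dtheta| <= dtheta_cutoff
      E = k (cos dtheta_cutoff - cos dtheta) otherwise
  which is continuous at the boundary and has dE/dtheta = k sin(dtheta),
  so the only zero-gradient point outside the flat bottom is the
  metastable state at dtheta = 180 deg;

* linear-capped spring for distance/position/tug restraints
      F = k |r - r0|   while below F_max, then constant F_max,
  with the energy taken as the unique C1 integral (quadratic, then linear).

Scripted operations (cis/trans flips, peptide-plane flips, secondary
structure bundles, rotamer targets, tugging) are compositions of these.
"""
from __future__ import annotations

import copy
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .structure import (
    CHI_ATOMS, FlexfitError, Residue, StructureModel, backbone_dihedrals,
    chi_dihedrals, measure_dihedral, wrap_angle,
)

log = logging.getLogger("flexfit")

# defaults; the flat-bottom widths follow the convention that backbone
# dihedrals may wander 30 deg and side-chain chi 15 deg before any
# restoring force applies.
DEFAULT_DIHEDRAL_K = 250.0       # kJ/mol
DEFAULT_DISTANCE_K = 500.0       # kJ/mol/A^2
DEFAULT_F_MAX = 100.0            # kJ/mol/A
CUTOFF_BACKBONE = 30.0           # deg, phi/psi/omega
CUTOFF_CHI = 15.0                # deg
FLIP_STEP_BUDGET = 500           # coordinate updates before a temporary
                                 # flip restraint is abandoned

# canonical secondary-structure geometry targets
SS_TARGETS = {
    "helix": {"phi": -57.0, "psi": -47.0, "o_n4": 3.0, "ca_ca2": 5.43},
    "strand": {"phi": -119.0, "psi": 113.0, "o_n4": None, "ca_ca2": 6.8},
}

#: most-common rotamer chi targets (degrees) for the chi-bearing residues;
#: a deliberately minimal table for scripted side-chain idealization.
COMMON_ROTAMERS = {
    "ARG": (-67.0, 180.0, 65.0, 85.0),
    "ASN": (-65.0, -40.0),
    "ASP": (-70.0, -15.0),
    "CYS": (-65.0,),
    "GLN": (-67.0, 180.0, -25.0),
    "GLU": (-67.0, 180.0, -10.0),
    "HIS": (-65.0, -70.0),
    "ILE": (-65.0, 170.0),
    "LEU": (-65.0, 175.0),
    "LYS": (-67.0, 180.0, 180.0, 180.0),
    "MET": (-67.0, 180.0, 75.0),
    "PHE": (-65.0, -85.0),
    "PRO": (30.0, -35.0),
    "SER": (64.0,),
    "THR": (62.0,),
    "TRP": (-65.0, 95.0),
    "TYR": (-65.0, -85.0),
    "VAL": (175.0,),
}


class RestraintError(FlexfitError):
    pass


# ---------------------------------------------------------------------------
# dihedral geometry with analytic gradient
# ---------------------------------------------------------------------------

def dihedral_and_gradient(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Dihedral angles (radians) and d(theta)/d(positions) for quadruples.

    ``p`` has shape (M, 4, 3); returns (theta (M,), grad (M, 4, 3)).
    The gradient rows sum to zero (translation invariance).
    """
    p = np.asarray(p, dtype=float)
    single = p.ndim == 2
    if single:
        p = p[None]
    b1 = p[:, 1] - p[:, 0]
    b2 = p[:, 2] - p[:, 1]
    b3 = p[:, 3] - p[:, 2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=1)
    n1sq = np.einsum("ij,ij->i", n1, n1)
    n2sq = np.einsum("ij,ij->i", n2, n2)
    if np.any(n1sq < 1e-18) or np.any(n2sq < 1e-18):
        raise RestraintError("degenerate dihedral geometry")
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2 / b2n[:, None])
    x = np.einsum("ij,ij->i", n1, n2)
    theta = np.arctan2(y, x)

    dp1 = -(b2n / n1sq)[:, None] * n1
    dp4 = (b2n / n2sq)[:, None] * n2
    t = np.einsum("ij,ij->i", b1, b2) / (b2n ** 2)
    s = np.einsum("ij,ij->i", b3, b2) / (b2n ** 2)
    dp2 = -(1.0 + t)[:, None] * dp1 + s[:, None] * dp4
    dp3 = t[:, None] * dp1 - (1.0 + s)[:, None] * dp4
    grad = np.stack([dp1, dp2, dp3, dp4], axis=1)
    if single:
        return theta[0], grad[0]
    return theta, grad


# ---------------------------------------------------------------------------
# restraint types
# ---------------------------------------------------------------------------

AtomKey = tuple  # (chain_id, seq_number, insertion_code, atom_name)


@dataclass
class DihedralRestraint:
    atoms: tuple[AtomKey, AtomKey, AtomKey, AtomKey]
    kind: str                      # phi | psi | omega | chi1..chi4
    target: float                  # degrees
    k: float = DEFAULT_DIHEDRAL_K
    cutoff: float = CUTOFF_BACKBONE
    enabled: bool = True
    temporary: bool = False

    def __post_init__(self):
        if not (0.0 <= self.cutoff < 180.0):
            raise RestraintError("dihedral cutoff must be in [0, 180) deg")
        if self.k < 0:
            raise RestraintError("k must be non-negative")
        self.target = wrap_angle(self.target)

    def delta(self, theta_deg: float) -> float:
        return wrap_angle(theta_deg - self.target)

    def energy_forces(self, positions) -> tuple[float, np.ndarray]:
        """Energy (kJ/mol) and forces (4, 3) on the four atoms."""
        theta, grad = dihedral_and_gradient(np.asarray(positions))
        dtheta = math.radians(self.delta(math.degrees(theta)))
        cut = math.radians(self.cutoff)
        if abs(dtheta) <= cut or self.k == 0 or not self.enabled:
            return 0.0, np.zeros((4, 3))
        e = self.k * (math.cos(cut) - math.cos(dtheta))
        dE_dtheta = self.k * math.sin(dtheta)
        return e, -dE_dtheta * grad

    def satisfied(self, theta_deg: float, tolerance: float | None = None) -> bool:
        tol = self.cutoff if tolerance is None else tolerance
        return abs(self.delta(theta_deg)) <= tol


def dihedral_restraint_energy(restraint: DihedralRestraint,
                              positions) -> tuple[float, np.ndarray]:
    """Functional form of :meth:`DihedralRestraint.energy_forces`."""
    return restraint.energy_forces(positions)


@dataclass
class LinearCappedRestraint:
    kind: str                       # distance | position | tug
    atoms: tuple[AtomKey, ...]      # two for distance, one otherwise
    target: np.ndarray | None = None  # 3-vector for position/tug
    r0: float = 0.0
    k: float = DEFAULT_DISTANCE_K
    f_max: float = DEFAULT_F_MAX
    enabled: bool = True

    def __post_init__(self):
        if self.kind not in ("distance", "position", "tug"):
            raise RestraintError(f"unknown restraint kind {self.kind!r}")
        if self.k < 0 or self.f_max <= 0 or self.r0 < 0:
            raise RestraintError("require k >= 0, F_max > 0, r0 >= 0")
        if self.kind == "distance":
            if len(self.atoms) != 2:
                raise RestraintError("distance restraint needs two atoms")
        else:
            if len(self.atoms) != 1 or self.target is None:
                raise RestraintError(f"{self.kind} restraint needs one atom "
                                     "and a target point")
            self.target = np.asarray(self.target, dtype=float)
            self.r0 = 0.0

    @property
    def crossover(self) -> float:
        return self.f_max / self.k if self.k > 0 else math.inf

    def energy_force_scalar(self, r: float) -> tuple[float, float]:
        """Energy and force *magnitude* at separation r (direction is the
        caller's job: the force always pulls toward r0 / the target)."""
        d = abs(r - self.r0)
        rc = self.crossover
        if d <= rc:
            return 0.5 * self.k * d * d, self.k * d
        e_c = 0.5 * self.k * rc * rc
        return e_c + self.f_max * (d - rc), self.f_max


def linear_capped_force(r: float, r0: float, k: float, f_max: float) -> float:
    """Force magnitude of the harmonic-then-constant restraint law."""
    if r < 0 or r0 < 0 or k < 0 or f_max <= 0:
        raise RestraintError("negative input to linear_capped_force")
    return min(k * abs(r - r0), f_max)


def linear_capped_energy(r: float, r0: float, k: float, f_max: float) -> float:
    """C1-consistent energy integral of :func:`linear_capped_force`."""
    if r < 0 or r0 < 0 or k < 0 or f_max <= 0:
        raise RestraintError("negative input to linear_capped_energy")
    d = abs(r - r0)
    rc = f_max / k if k > 0 else math.inf
    if d <= rc:
        return 0.5 * k * d * d
    return 0.5 * k * rc * rc + f_max * (d - rc)


# ---------------------------------------------------------------------------
# the restraint set
# ---------------------------------------------------------------------------

@dataclass
class _TempGroup:
    keys: list
    created_frame: int
    budget: int = FLIP_STEP_BUDGET
    label: str = "peptide-plane flip"


class RestraintSet:
    """All active restraints on a model, with bundle bookkeeping.

    At most one restraint is active per (residue, dihedral kind), per atom
    pair (distance) and per (atom, kind) for position/tug; adding again
    replaces.  Bundles group restraints created by one scripted operation
    so they can be released as a unit.
    """

    def __init__(self):
        self.dihedrals: dict[tuple, DihedralRestraint] = {}   # (res_key, kind)
        self.distances: dict[frozenset, LinearCappedRestraint] = {}
        self.positions: dict[tuple, LinearCappedRestraint] = {}  # (atom, kind)
        self.bundles: dict[str, list[tuple[str, object]]] = {}
        self.temp_groups: list[_TempGroup] = []
        self.version = 0
        self._bundle_counter = 0

    # -- mutation helpers --------------------------------------------------
    def _touch(self):
        self.version += 1

    def add_dihedral(self, res_key, restraint: DihedralRestraint,
                     bundle: str | None = None):
        key = (tuple(res_key), restraint.kind)
        self.dihedrals[key] = restraint
        if bundle:
            self.bundles[bundle].append(("dihedral", key))
        self._touch()
        return key

    def add_distance(self, restraint: LinearCappedRestraint,
                     bundle: str | None = None):
        key = frozenset(restraint.atoms)
        self.distances[key] = restraint
        if bundle:
            self.bundles[bundle].append(("distance", key))
        self._touch()
        return key

    def add_position(self, restraint: LinearCappedRestraint,
                     bundle: str | None = None):
        key = (restraint.atoms[0], restraint.kind)
        self.positions[key] = restraint
        if bundle:
            self.bundles[bundle].append(("position", key))
        self._touch()
        return key

    def new_bundle(self, label: str = "bundle") -> str:
        self._bundle_counter += 1
        bid = f"{label}-{self._bundle_counter}"
        self.bundles[bid] = []
        return bid

    def release_bundle(self, bundle_id: str) -> int:
        """Remove all and only the bundle's members; returns count removed."""
        members = self.bundles.pop(bundle_id, None)
        if members is None:
            raise RestraintError(f"unknown bundle {bundle_id!r}")
        n = 0
        for table_name, key in members:
            table = {"dihedral": self.dihedrals, "distance": self.distances,
                     "position": self.positions}[table_name]
            if key in table:
                del table[key]
                n += 1
        self._touch()
        return n

    def remove_for_residues(self, res_keys: Sequence[tuple]) -> int:
        """Drop every restraint touching any atom of the given residues."""
        res_keys = {tuple(k) for k in res_keys}

        def touches(atom_key):
            return tuple(atom_key[:3]) in res_keys

        n = 0
        for key in [k for k in self.dihedrals if tuple(k[0]) in res_keys]:
            del self.dihedrals[key]
            n += 1
        for key in [k for k, r in self.distances.items()
                    if any(touches(a) for a in r.atoms)]:
            del self.distances[key]
            n += 1
        for key in [k for k, r in self.positions.items()
                    if touches(r.atoms[0])]:
            del self.positions[key]
            n += 1
        if n:
            self._touch()
        return n

    def __len__(self) -> int:
        return len(self.dihedrals) + len(self.distances) + len(self.positions)

    def copy(self) -> "RestraintSet":
        return copy.deepcopy(self)

    # -- temporary (auto-releasing) restraints ----------------------------
    def check_temporaries(self, model: StructureModel, frame: int) -> None:
        """Release temporary groups whose targets are satisfied, or whose
        step budget has expired (with a logged warning)."""
        still = []
        for grp in self.temp_groups:
            restraints = [self.dihedrals.get(k) for k in grp.keys]
            restraints = [r for r in restraints if r is not None]
            if not restraints:
                continue
            ok = all(self._dihedral_satisfied(model, key, r)
                     for key, r in zip(grp.keys, restraints))
            if ok:
                for key in grp.keys:
                    self.dihedrals.pop(key, None)
                self._touch()
                log.info("%s: targets satisfied, restraints released", grp.label)
            elif frame - grp.created_frame >= grp.budget:
                for key in grp.keys:
                    self.dihedrals.pop(key, None)
                self._touch()
                log.warning("%s: targets not met within %d coordinate updates; "
                            "restraints removed", grp.label, grp.budget)
            else:
                still.append(grp)
        self.temp_groups = still

    @staticmethod
    def _dihedral_satisfied(model, key, restraint) -> bool:
        res = model.residue(key[0])
        positions = _dihedral_positions(model, res, restraint)
        if positions is None:
            return False
        theta = measure_dihedral(*positions)
        return restraint.satisfied(theta)

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        def enc_d(key, r: DihedralRestraint):
            return {"residue": list(key[0]), "kind": r.kind,
                    "atoms": [list(a) for a in r.atoms], "target": r.target,
                    "k": r.k, "cutoff": r.cutoff, "enabled": r.enabled,
                    "temporary": r.temporary}

        def enc_l(r: LinearCappedRestraint):
            return {"kind": r.kind, "atoms": [list(a) for a in r.atoms],
                    "target": None if r.target is None else list(r.target),
                    "r0": r.r0, "k": r.k, "f_max": r.f_max,
                    "enabled": r.enabled}

        doc = {
            "dihedrals": [enc_d(k, r) for k, r in self.dihedrals.items()],
            "linear": [enc_l(r) for r in
                       list(self.distances.values()) + list(self.positions.values())],
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RestraintSet":
        doc = json.loads(text)
        rset = cls()
        for d in doc.get("dihedrals", []):
            r = DihedralRestraint(
                atoms=tuple(tuple(a) for a in d["atoms"]), kind=d["kind"],
                target=d["target"], k=d["k"], cutoff=d["cutoff"],
                enabled=d["enabled"], temporary=d["temporary"])
            rset.add_dihedral(tuple(d["residue"]), r)
        for d in doc.get("linear", []):
            r = LinearCappedRestraint(
                kind=d["kind"], atoms=tuple(tuple(a) for a in d["atoms"]),
                target=d["target"], r0=d["r0"], k=d["k"], f_max=d["f_max"],
                enabled=d["enabled"])
            if r.kind == "distance":
                rset.add_distance(r)
            else:
                rset.add_position(r)
        return rset


def _dihedral_positions(model: StructureModel, residue: Residue,
                        restraint: DihedralRestraint):
    idx = model.atom_index()
    flat = model.atom_list()
    try:
        return [flat[idx[tuple(a)]][1].position for a in restraint.atoms]
    except KeyError:
        return None


# ---------------------------------------------------------------------------
# scripted operations
# ---------------------------------------------------------------------------

def _atom_key(res: Residue, name: str) -> AtomKey:
    return res.key + (name,)


def add_default_omega_restraints(rset: RestraintSet, model: StructureModel,
                                 k: float = DEFAULT_DIHEDRAL_K) -> int:
    """Restrain every omega dihedral to its nearer planar state (0 or 180).

    This is the only restraint applied by default on model load: peptide
    geometry must be protected, because restraint/tug forces can otherwise
    flip trans bonds to cis inadvertently.
    """
    n = 0
    for rec in backbone_dihedrals(model):
        if rec.kind != "omega":
            continue
        target = 0.0 if abs(rec.angle) < 90.0 else 180.0
        prev_ca, prev_c, this_n, this_ca = rec.atoms
        res = rec.residue
        chain = model.chains[res.chain_id]
        aa = [r for r in chain if r.is_amino_acid]
        prev = aa[aa.index(res) - 1]
        restraint = DihedralRestraint(
            atoms=(_atom_key(prev, "CA"), _atom_key(prev, "C"),
                   _atom_key(res, "N"), _atom_key(res, "CA")),
            kind="omega", target=target, k=k, cutoff=CUTOFF_BACKBONE)
        rset.add_dihedral(res.key, restraint)
        n += 1
    return n


def flip_cis_trans(rset: RestraintSet, model: StructureModel,
                   residue: Residue | tuple) -> DihedralRestraint:
    """Toggle the omega restraint target of a residue between 0 and 180 deg.

    The new target is always the planar state *farther* from the current
    omega, so repeated application is an involution.
    """
    res = residue if isinstance(residue, Residue) else model.residue(residue)
    key = (res.key, "omega")
    restraint = rset.dihedrals.get(key)
    if restraint is None:
        raise RestraintError(f"residue {res.key} has no omega restraint "
                             "(chain N-terminus, chain break, or restraints "
                             "not initialized)")
    restraint.target = 0.0 if abs(restraint.target) > 90.0 else 180.0
    rset._touch()
    return restraint


def flip_peptide_plane(rset: RestraintSet, model: StructureModel,
                       residue: Residue | tuple,
                       frame: int = 0,
                       budget: int = FLIP_STEP_BUDGET,
                       k: float = DEFAULT_DIHEDRAL_K) -> list[DihedralRestraint]:
    """Add temporary restraints that flip the peptide plane N-terminal to
    ``residue``: targets are psi(i-1)+180 and phi(i)+180.

    The pair auto-releases once both dihedrals are within the flat-bottom
    cutoff of their targets, or with a warning after ``budget`` coordinate
    updates (see :meth:`RestraintSet.check_temporaries`).
    """
    res = residue if isinstance(residue, Residue) else model.residue(residue)
    chain = [r for r in model.chains[res.chain_id] if r.is_amino_acid]
    i = chain.index(res)
    if i == 0:
        raise RestraintError("no peptide bond N-terminal to a chain-leading residue")
    prev = chain[i - 1]
    recs = {(r.residue.key, r.kind): r for r in backbone_dihedrals(model)}
    psi_rec = recs.get((prev.key, "psi"))
    phi_rec = recs.get((res.key, "phi"))
    if psi_rec is None or phi_rec is None:
        raise RestraintError(f"phi/psi around the peptide before {res.key} "
                             "are not measurable")
    made = []
    keys = []
    for rec, owner in ((psi_rec, prev), (phi_rec, res)):
        restraint = DihedralRestraint(
            atoms=tuple(_atom_key_for(owner_model=model, atom=a) for a in rec.atoms),
            kind=rec.kind, target=wrap_angle(rec.angle + 180.0),
            k=k, cutoff=CUTOFF_BACKBONE, temporary=True)
        keys.append(rset.add_dihedral(owner.key, restraint))
        made.append(restraint)
    rset.temp_groups.append(_TempGroup(keys=keys, created_frame=frame,
                                       budget=budget))
    return made


_ATOM_KEY_CACHE: dict[int, tuple[int, dict]] = {}


def _atom_key_for(owner_model: StructureModel, atom) -> AtomKey:
    """Recover the (chain, seq, icode, name) key owning an Atom object."""
    cached = _ATOM_KEY_CACHE.get(id(owner_model))
    if cached is None or cached[0] != owner_model.n_atoms:
        table = {id(a): r.key + (a.name,) for r, a in owner_model.atoms()}
        _ATOM_KEY_CACHE[id(owner_model)] = (owner_model.n_atoms, table)
        if len(_ATOM_KEY_CACHE) > 8:
            _ATOM_KEY_CACHE.pop(next(iter(_ATOM_KEY_CACHE)))
        cached = _ATOM_KEY_CACHE[id(owner_model)]
    key = cached[1].get(id(atom))
    if key is None:
        raise RestraintError("atom not in model")
    return key


def restrain_secondary_structure(rset: RestraintSet, model: StructureModel,
                                 selection: Sequence, kind: str,
                                 k_dihedral: float = DEFAULT_DIHEDRAL_K,
                                 k_distance: float = DEFAULT_DISTANCE_K,
                                 f_max: float = DEFAULT_F_MAX) -> str:
    """Impose canonical helix/strand geometry on a contiguous residue run.

    Adds phi/psi dihedral restraints at the canonical targets plus, where
    the partner exists within the run, O(n)-N(n+4) (helix only) and
    CA(n)-CA(n+2) distance restraints.  Returns a bundle id that
    :meth:`RestraintSet.release_bundle` removes as a unit.
    """
    if kind not in SS_TARGETS:
        raise RestraintError(f"unknown secondary-structure kind {kind!r}")
    run = [r if isinstance(r, Residue) else model.residue(r) for r in selection]
    if len(run) < 3:
        raise RestraintError("secondary-structure run must have >= 3 residues")
    chain = model.chains[run[0].chain_id]
    idx = [chain.index(r) for r in run]
    if any(r.chain_id != run[0].chain_id for r in run) or \
            idx != list(range(idx[0], idx[0] + len(run))):
        raise RestraintError("selection is not a contiguous run in one chain")
    t = SS_TARGETS[kind]
    bundle = rset.new_bundle(f"ss-{kind}")
    recs = {(r.residue.key, r.kind): r for r in backbone_dihedrals(model)}
    for res in run:
        for dkind in ("phi", "psi"):
            rec = recs.get((res.key, dkind))
            if rec is None:
                continue
            restraint = DihedralRestraint(
                atoms=tuple(_atom_key_for(model, a) for a in rec.atoms),
                kind=dkind, target=t[dkind], k=k_dihedral,
                cutoff=CUTOFF_BACKBONE)
            rset.add_dihedral(res.key, restraint, bundle=bundle)
    for i, res in enumerate(run):
        if t["o_n4"] is not None and i + 4 < len(run):
            partner = run[i + 4]
            if res.atom("O") is not None and partner.atom("N") is not None:
                rset.add_distance(LinearCappedRestraint(
                    kind="distance",
                    atoms=(_atom_key(res, "O"), _atom_key(partner, "N")),
                    r0=t["o_n4"], k=k_distance, f_max=f_max), bundle=bundle)
        if i + 2 < len(run):
            partner = run[i + 2]
            if res.atom("CA") is not None and partner.atom("CA") is not None:
                rset.add_distance(LinearCappedRestraint(
                    kind="distance",
                    atoms=(_atom_key(res, "CA"), _atom_key(partner, "CA")),
                    r0=t["ca_ca2"], k=k_distance, f_max=f_max), bundle=bundle)
    return bundle


def apply_rotamer_target(rset: RestraintSet, model: StructureModel,
                         residue: Residue | tuple,
                         chi_targets: Sequence[float] | None = None,
                         k: float = DEFAULT_DIHEDRAL_K) -> list[DihedralRestraint]:
    """Restrain the side-chain chi dihedrals of a residue toward a rotamer.

    ``chi_targets`` defaults to the bundled most-common rotamer for the
    residue type.  Each chi restraint uses the 15 deg side-chain cutoff;
    re-application replaces previous chi restraints rather than stacking.
    """
    res = residue if isinstance(residue, Residue) else model.residue(residue)
    n_chi = len(CHI_ATOMS.get(res.name, []))
    if n_chi == 0:
        raise RestraintError(f"{res.name} has no chi dihedrals")
    if chi_targets is None:
        chi_targets = COMMON_ROTAMERS[res.name]
    if len(chi_targets) > n_chi:
        raise RestraintError(f"{res.name} has only {n_chi} chi dihedrals")
    made = []
    for i, target in enumerate(chi_targets):
        quad = CHI_ATOMS[res.name][i]
        if any(res.atom(nm) is None for nm in quad):
            raise RestraintError(f"{res.key}: atoms for chi{i + 1} missing")
        restraint = DihedralRestraint(
            atoms=tuple(_atom_key(res, nm) for nm in quad),
            kind=f"chi{i + 1}", target=target, k=k, cutoff=CUTOFF_CHI)
        rset.add_dihedral(res.key, restraint)
        made.append(restraint)
    return made


def tug(rset: RestraintSet, model: StructureModel, atom_key: AtomKey,
        target, k: float = DEFAULT_DISTANCE_K,
        f_max: float = DEFAULT_F_MAX) -> LinearCappedRestraint:
    """Attach (or retarget) a moving position restraint on a heavy atom.

    The force law is identical to a position restraint; the caller may
    update ``.target`` at every coordinate update.  At most one tug exists
    per atom.
    """
    idx = model.atom_index()
    atom_key = tuple(atom_key)
    if atom_key not in idx:
        raise RestraintError(f"no atom {atom_key} in model")
    atom = model.atom_list()[idx[atom_key]][1]
    if atom.is_hydrogen:
        raise RestraintError("only heavy atoms may be tugged")
    restraint = LinearCappedRestraint(kind="tug", atoms=(atom_key,),
                                      target=np.asarray(target, dtype=float),
                                      k=k, f_max=f_max)
    rset.add_position(restraint)
    return restraint
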