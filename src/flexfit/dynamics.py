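"""Minimal pluggable simulation engine for restraint-guided fitting.

The engine sums additive :class:`ForceProvider` contributions:

* a simplified geometry-maintenance force field (harmonic bonds and
  angles at ideal values, periodic planarity terms for peptide omega
  planes and aromatic rings, and a capped soft-sphere 1/r^12 repulsion) —
  deliberately free of electrostatics and solvent, since the restraint,
  map and validation layers are engine-independent and a full
  biomolecular force field can be plugged in behind the same contract;
* all active restraints;
* any attached density-map potentials.

Integration is BAOAB Langevin (1 fs timestep, 10 ps^-1 friction by
default); at T = 0 it reduces to damped settling.  A "coordinate update"
is 20 timesteps: moving restraints (tugs, register-shift schedules)
advance and temporary restraints are checked on that cadence, and
validation summaries refresh every ten coordinate updates.

Units: kJ/mol, angstrom, femtosecond, kelvin, atomic mass units.
"""
from __future__ import annotations

import copy
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import validation
from .map_potential import DensityMapPotential, mdff_energy
from .restraints import RestraintSet, dihedral_and_gradient
from .structure import (
    ANGLE_CA_C_N, ANGLE_C_N_CA, ANGLE_O_C_N, BOND_C_N, FlexfitError,
    StructureModel, _ccd_heavy, residues_bonded,
)

log = logging.getLogger("flexfit")

KB = 0.0083144621           # kJ/mol/K
FORCE_TO_ACC = 1e-4         # kJ/mol/A  ->  amu * A / fs^2

DEFAULT_TIMESTEP = 1.0      # fs
DEFAULT_FRICTION = 0.01     # fs^-1  (10 ps^-1)
DEFAULT_TEMPERATURE = 100.0 # K
COORD_UPDATE_INTERVAL = 20  # timesteps per coordinate update
VALIDATION_CADENCE = 10     # coordinate updates per validation refresh

K_BOND = 4000.0             # kJ/mol/A^2
BOND_FORCE_CAP = 2000.0     # kJ/mol/A: a badly stretched (re-ligating)
                            # bond pulls with constant force instead of a
                            # divergent one
K_ANGLE = 400.0             # kJ/mol/rad^2
K_OMEGA_PLANE = 60.0        # kJ/mol, E = k (1 - cos 2*omega)
K_RING_PLANE = 40.0         # kJ/mol per ring torsion
NB_SIGMA = 2.7              # A
NB_EPSILON = 4.0            # kJ/mol
NB_CUTOFF = 3.2             # A
NB_FORCE_CAP = 1.0e4        # kJ/mol/A, survives bad starting clashes

# The force field ligates consecutive residues whose C-N separation is
# below this reach, so geometry stretched by an error (e.g. a register
# shift squeezing or opening one peptide) is pulled back together during
# settling; true chain breaks are farther apart and stay free.
FF_LIGATE_CUTOFF = 5.0      # A

MASSES = {"H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
          "S": 32.06, "P": 30.974, "SE": 78.97, "F": 18.998, "CL": 35.45,
          "BR": 79.904, "I": 126.9, "NA": 22.99, "K": 39.098, "MG": 24.305,
          "CA": 40.078, "MN": 54.938, "FE": 55.845, "CO": 58.933,
          "NI": 58.693, "CU": 63.546, "ZN": 65.38}

RING_ATOMS = {
    "PHE": [("CG", "CD1", "CE1", "CZ", "CE2", "CD2")],
    "TYR": [("CG", "CD1", "CE1", "CZ", "CE2", "CD2")],
    "HIS": [("CG", "ND1", "CE1", "NE2", "CD2")],
    "TRP": [("CG", "CD1", "NE1", "CE2", "CD2"),
            ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3")],
    "PRO": [],  # the pyrrolidine ring is non-planar; bonds/angles suffice
}

INTER_RESIDUE_ANGLES = {
    ("CA", "C", "N"): ANGLE_CA_C_N,
    ("O", "C", "N"): ANGLE_O_C_N,
    ("C", "N", "CA"): ANGLE_C_N_CA,
}
PROLINE_N_ANGLE = (("C", "N", "CD"), 125.0)

# backbone terms use the same ideal constants as the peptide builder, so a
# freshly built fixture sits at the minimum of every bonded term
BACKBONE_BOND_OVERRIDES = {
    frozenset(("N", "CA")): 1.458,
    frozenset(("CA", "C")): 1.525,
    frozenset(("C", "O")): 1.231,
}
BACKBONE_ANGLE_OVERRIDES = {
    ("N", "CA", "C"): 111.2,
    ("CA", "C", "O"): 120.8,
}


class SimulationError(FlexfitError):
    pass


class ForceProvider:
    """Contract: evaluate(positions) -> (energy, per-atom forces)."""

    name = "provider"

    def evaluate(self, positions: np.ndarray) -> tuple[float, np.ndarray]:
        raise NotImplementedError


# ---------------------------------------------------------------------------
# simplified geometry-maintenance force field
# ---------------------------------------------------------------------------

class SimplifiedForceField(ForceProvider):
    """Bonds/angles at ideal values, planarity torsions, capped repulsion.

    Ideal bond lengths and angles come from the same ideal component
    geometry used by the fixture builder, so an ideal fixture sits at the
    minimum of every bonded term.
    """

    name = "forcefield"

    def __init__(self, model: StructureModel):
        self.model = model
        self._build(model)

    def _build(self, model: StructureModel) -> None:
        idx = model.atom_index()
        flat = model.atom_list()
        n = len(flat)
        bonds: list[tuple[int, int, float]] = []
        unknown: list[str] = []
        ccd_cache: dict[str, tuple] = {}

        def ccd(resname):
            if resname not in ccd_cache:
                names, coords, elements, bond_list = _ccd_heavy(resname)
                ccd_cache[resname] = ({nm: c for nm, c in zip(names, coords)},
                                      bond_list)
            return ccd_cache[resname]

        # intra-residue bonds from ideal component geometry
        for res in model.residues():
            present = {a.name for a in res.atoms if not a.is_hydrogen}
            if len(present) <= 1:
                continue  # ions, single-atom het groups: nonbonded only
            try:
                ref, bond_list = ccd(res.name)
            except FlexfitError:
                unknown.append(f"{res.name} at {res.key}")
                continue
            for a, b in bond_list:
                if a in present and b in present:
                    r0 = BACKBONE_BOND_OVERRIDES.get(
                        frozenset((a, b)),
                        float(np.linalg.norm(ref[a] - ref[b])))
                    bonds.append((idx[res.key + (a,)], idx[res.key + (b,)], r0))
        if unknown:
            raise SimulationError(
                "unknown residue type(s): " + ", ".join(sorted(set(unknown))))

        # inter-residue peptide bonds
        torsions: list[tuple[int, int, int, int, float]] = []
        extra_angles: list[tuple[int, int, int, float]] = []
        for chain in model.chains.values():
            aa = [r for r in chain if r.is_amino_acid]
            for r1, r2 in zip(aa, aa[1:]):
                c_at, n_at = r1.atom("C"), r2.atom("N")
                if c_at is None or n_at is None or \
                        float(np.linalg.norm(c_at.position - n_at.position)) \
                        > FF_LIGATE_CUTOFF:
                    continue
                c, n2 = idx[r1.key + ("C",)], idx[r2.key + ("N",)]
                bonds.append((c, n2, BOND_C_N))
                inter = dict(INTER_RESIDUE_ANGLES)
                if r2.name == "PRO":
                    inter[PROLINE_N_ANGLE[0]] = PROLINE_N_ANGLE[1]
                for names, theta0 in inter.items():
                    a_res, b_res, c_res = (r1, r1, r2) if names[1] == "C" \
                        else (r1, r2, r2)
                    keys = (a_res.key + (names[0],), b_res.key + (names[1],),
                            c_res.key + (names[2],))
                    if all(k in idx for k in keys):
                        extra_angles.append((idx[keys[0]], idx[keys[1]],
                                             idx[keys[2]], theta0))
                # omega plane
                quad = (r1.key + ("CA",), r1.key + ("C",),
                        r2.key + ("N",), r2.key + ("CA",))
                if all(k in idx for k in quad):
                    torsions.append(tuple(idx[k] for k in quad) + (K_OMEGA_PLANE,))

        # angles from the bond graph; ideal values from component geometry
        graph: dict[int, set[int]] = {i: set() for i in range(n)}
        for i, j, _ in bonds:
            graph[i].add(j)
            graph[j].add(i)
        seen_angles = {(a, b, c) for a, b, c, _ in extra_angles}
        angles = list(extra_angles)
        key_of = {i: (flat[i][0], flat[i][1]) for i in range(n)}
        for j in range(n):
            nb = sorted(graph[j])
            for ai in range(len(nb)):
                for ci in range(ai + 1, len(nb)):
                    i, k = nb[ai], nb[ci]
                    if (i, j, k) in seen_angles or (k, j, i) in seen_angles:
                        continue
                    ri, rj, rk = key_of[i][0], key_of[j][0], key_of[k][0]
                    if ri is rj is rk:
                        ref, _ = ccd(rj.name)
                        ni, nj, nk = key_of[i][1].name, key_of[j][1].name, key_of[k][1].name
                        if (ni, nj, nk) in BACKBONE_ANGLE_OVERRIDES or \
                                (nk, nj, ni) in BACKBONE_ANGLE_OVERRIDES:
                            theta0 = BACKBONE_ANGLE_OVERRIDES.get(
                                (ni, nj, nk),
                                BACKBONE_ANGLE_OVERRIDES.get((nk, nj, ni)))
                        elif ni in ref and nj in ref and nk in ref:
                            v1, v2 = ref[ni] - ref[nj], ref[nk] - ref[nj]
                            theta0 = math.degrees(math.acos(np.clip(
                                np.dot(v1, v2)
                                / (np.linalg.norm(v1) * np.linalg.norm(v2)),
                                -1, 1)))
                        else:
                            theta0 = 110.0
                    else:
                        names = (key_of[i][1].name, key_of[j][1].name,
                                 key_of[k][1].name)
                        theta0 = INTER_RESIDUE_ANGLES.get(
                            names, INTER_RESIDUE_ANGLES.get(names[::-1], 120.0))
                    angles.append((i, j, k, theta0))

        # ring planarity torsions
        for res in model.residues():
            for ring in RING_ATOMS.get(res.name, []):
                keys = [res.key + (nm,) for nm in ring]
                if not all(k in idx for k in keys):
                    continue
                m = len(ring)
                for s in range(m):
                    quad = tuple(idx[keys[(s + d) % m]] for d in range(4))
                    torsions.append(quad + (K_RING_PLANE,))

        self.bond_idx = np.array([(i, j) for i, j, _ in bonds], dtype=int).reshape(-1, 2)
        self.bond_r0 = np.array([r0 for _, _, r0 in bonds])
        self.angle_idx = np.array([(i, j, k) for i, j, k, _ in angles],
                                  dtype=int).reshape(-1, 3)
        self.angle_theta0 = np.radians([t for _, _, _, t in angles])
        self.torsion_idx = np.array([q[:4] for q in torsions], dtype=int).reshape(-1, 4)
        self.torsion_k = np.array([q[4] for q in torsions])

        # nonbonded: heavy atoms, excluding pairs within 3 bonds
        self.heavy = np.array([not a.is_hydrogen for _, a in flat])
        excl: set[frozenset] = set()
        for i in range(n):
            frontier = {i}
            reached = {i}
            for _ in range(3):
                frontier = {k for f in frontier for k in graph[f]} - reached
                for k in frontier:
                    excl.add(frozenset((i, k)))
                reached |= frontier
        self.exclusions = excl
        self._nb_shift = NB_EPSILON * (NB_SIGMA / NB_CUTOFF) ** 12

    # -- evaluation --------------------------------------------------------
    def evaluate(self, pos: np.ndarray) -> tuple[float, np.ndarray]:
        e = 0.0
        forces = np.zeros_like(pos)
        if len(self.bond_idx):
            i, j = self.bond_idx[:, 0], self.bond_idx[:, 1]
            d = pos[i] - pos[j]
            r = np.linalg.norm(d, axis=1)
            dr = r - self.bond_r0
            # harmonic, switching to constant force at large stretch
            rc = BOND_FORCE_CAP / K_BOND
            ad = np.abs(dr)
            e_h = 0.5 * K_BOND * dr * dr
            e_l = 0.5 * K_BOND * rc * rc + BOND_FORCE_CAP * (ad - rc)
            e += float(np.sum(np.where(ad <= rc, e_h, e_l)))
            fmag = np.minimum(K_BOND * ad, BOND_FORCE_CAP) * np.sign(dr)
            f = (-fmag / np.maximum(r, 1e-12))[:, None] * d
            np.add.at(forces, i, f)
            np.add.at(forces, j, -f)
        if len(self.angle_idx):
            i, j, k = (self.angle_idx[:, c] for c in range(3))
            rij = pos[i] - pos[j]
            rkj = pos[k] - pos[j]
            nij = np.linalg.norm(rij, axis=1)
            nkj = np.linalg.norm(rkj, axis=1)
            uij = rij / nij[:, None]
            ukj = rkj / nkj[:, None]
            cos = np.clip(np.einsum("ij,ij->i", uij, ukj), -1.0, 1.0)
            theta = np.arccos(cos)
            sin = np.sqrt(np.maximum(1.0 - cos * cos, 1e-12))
            dth = theta - self.angle_theta0
            e += 0.5 * K_ANGLE * float(np.sum(dth * dth))
            coef = (-K_ANGLE * dth / sin)
            dth_di = -(ukj - cos[:, None] * uij) / nij[:, None]
            dth_dk = -(uij - cos[:, None] * ukj) / nkj[:, None]
            fi = coef[:, None] * dth_di
            fk = coef[:, None] * dth_dk
            np.add.at(forces, i, fi)
            np.add.at(forces, k, fk)
            np.add.at(forces, j, -(fi + fk))
        if len(self.torsion_idx):
            quads = pos[self.torsion_idx]
            theta, grad = dihedral_and_gradient(quads)
            # E = k (1 - cos 2 theta): minima at both planar states
            e += float(np.sum(self.torsion_k * (1.0 - np.cos(2.0 * theta))))
            dE = 2.0 * self.torsion_k * np.sin(2.0 * theta)
            f = -dE[:, None, None] * grad
            for c in range(4):
                np.add.at(forces, self.torsion_idx[:, c], f[:, c])
        e_nb, f_nb = self._nonbonded(pos)
        return e + e_nb, forces + f_nb

    def _nonbonded(self, pos: np.ndarray) -> tuple[float, np.ndarray]:
        from scipy.spatial import cKDTree

        heavy_idx = np.nonzero(self.heavy)[0]
        tree = cKDTree(pos[heavy_idx])
        pairs = tree.query_pairs(NB_CUTOFF, output_type="ndarray")
        forces = np.zeros_like(pos)
        if len(pairs) == 0:
            return 0.0, forces
        gi = heavy_idx[pairs[:, 0]]
        gj = heavy_idx[pairs[:, 1]]
        keep = np.array([frozenset((a, b)) not in self.exclusions
                         for a, b in zip(gi, gj)])
        gi, gj = gi[keep], gj[keep]
        if len(gi) == 0:
            return 0.0, forces
        d = pos[gi] - pos[gj]
        r = np.linalg.norm(d, axis=1)
        r = np.maximum(r, 0.2)
        sr12 = (NB_SIGMA / r) ** 12
        e = float(np.sum(NB_EPSILON * sr12 - self._nb_shift))
        fmag = np.minimum(12.0 * NB_EPSILON * sr12 / r, NB_FORCE_CAP)
        f = (fmag / r)[:, None] * d
        np.add.at(forces, gi, f)
        np.add.at(forces, gj, -f)
        return e, forces

    def min_nonbonded_distance(self, pos: np.ndarray) -> float:
        from scipy.spatial import cKDTree

        heavy_idx = np.nonzero(self.heavy)[0]
        tree = cKDTree(pos[heavy_idx])
        best = math.inf
        for a, b in tree.query_pairs(6.0):
            gi, gj = heavy_idx[a], heavy_idx[b]
            if frozenset((gi, gj)) in self.exclusions:
                continue
            best = min(best, float(np.linalg.norm(pos[gi] - pos[gj])))
        return best


def simplified_forcefield(model: StructureModel) -> SimplifiedForceField:
    """Build the geometry-maintenance force field for a model."""
    return SimplifiedForceField(model)


# ---------------------------------------------------------------------------
# restraint and map providers
# ---------------------------------------------------------------------------

class RestraintForces(ForceProvider):
    """Evaluates the simulation's current restraint set (always live: the
    provider re-reads ``state.restraints``, so checkpoint restores and
    bundle releases take effect immediately)."""

    name = "restraints"

    def __init__(self, state: "SimulationState"):
        self.state = state
        self._version = -1
        self._cache = None

    def _compile(self):
        rset = self.state.restraints
        idx = self.state.model.atom_index()
        dihedrals = []
        for r in rset.dihedrals.values():
            if r.enabled and all(tuple(a) in idx for a in r.atoms):
                dihedrals.append((tuple(idx[tuple(a)] for a in r.atoms), r))
        distances = []
        for r in rset.distances.values():
            if r.enabled and all(tuple(a) in idx for a in r.atoms):
                distances.append((idx[tuple(r.atoms[0])],
                                  idx[tuple(r.atoms[1])], r))
        positions = []
        for r in rset.positions.values():
            if r.enabled and tuple(r.atoms[0]) in idx:
                positions.append((idx[tuple(r.atoms[0])], r))
        self._cache = (dihedrals, distances, positions)
        self._version = rset.version

    def evaluate(self, pos: np.ndarray) -> tuple[float, np.ndarray]:
        if self._cache is None or self._version != self.state.restraints.version:
            self._compile()
        dihedrals, distances, positions = self._cache
        e = 0.0
        forces = np.zeros_like(pos)
        for quad, r in dihedrals:
            er, fr = r.energy_forces(pos[list(quad)])
            e += er
            for c, ai in enumerate(quad):
                forces[ai] += fr[c]
        for i, j, r in distances:
            d = pos[i] - pos[j]
            dist = float(np.linalg.norm(d))
            er, fmag = r.energy_force_scalar(dist)
            e += er
            if dist > 1e-9:
                u = d / dist
                sgn = 1.0 if dist > r.r0 else -1.0
                forces[i] += -sgn * fmag * u
                forces[j] += sgn * fmag * u
        for i, r in positions:
            d = pos[i] - r.target
            dist = float(np.linalg.norm(d))
            er, fmag = r.energy_force_scalar(dist)
            e += er
            if dist > 1e-9:
                forces[i] += -fmag * d / dist
        return e, forces


class MapForces(ForceProvider):
    """A density-map potential acting on the model's heavy atoms."""

    name = "map"

    def __init__(self, potential: DensityMapPotential, model: StructureModel):
        self.potential = potential
        self.enabled = np.array([not a.is_hydrogen for _, a in model.atoms()])

    def evaluate(self, pos: np.ndarray) -> tuple[float, np.ndarray]:
        return mdff_energy(self.potential, pos, self.enabled)


# ---------------------------------------------------------------------------
# simulation state
# ---------------------------------------------------------------------------

@dataclass
class Checkpoint:
    """Snapshot of positions and the full restraint set."""
    positions: np.ndarray
    velocities: np.ndarray
    restraints: RestraintSet
    frame: int
    signature: tuple

    def to_json(self) -> str:
        return json.dumps({
            "positions": self.positions.tolist(),
            "velocities": self.velocities.tolist(),
            "restraints": json.loads(self.restraints.to_json()),
            "frame": self.frame,
            "signature": list(self.signature),
        })

    @classmethod
    def from_json(cls, text: str) -> "Checkpoint":
        doc = json.loads(text)
        return cls(positions=np.array(doc["positions"]),
                   velocities=np.array(doc["velocities"]),
                   restraints=RestraintSet.from_json(
                       json.dumps(doc["restraints"])),
                   frame=doc["frame"], signature=tuple(doc["signature"]))


class SimulationState:
    """Positions, velocities, masks, providers and schedules of one run."""

    def __init__(self, model: StructureModel,
                 restraints: RestraintSet | None = None,
                 mobile_keys=None,
                 temperature: float = DEFAULT_TEMPERATURE,
                 timestep: float = DEFAULT_TIMESTEP,
                 friction: float = DEFAULT_FRICTION,
                 seed: int = 0):
        if temperature < 0:
            raise SimulationError("temperature must be >= 0")
        self.model = model
        self.positions = model.positions()
        self.velocities = np.zeros_like(self.positions)
        self.restraints = restraints if restraints is not None else RestraintSet()
        self.temperature = float(temperature)
        self.timestep = float(timestep)
        self.friction = float(friction)
        self.coordinate_update_interval = COORD_UPDATE_INTERVAL
        self.validation_cadence = VALIDATION_CADENCE
        self.frame = 0           # coordinate updates completed
        self.step_count = 0
        self.seed = int(seed)
        self.rng = np.random.default_rng(seed)
        self.providers: list[ForceProvider] = []
        self.moving_updaters: list = []   # callables run each coordinate update
        self.validation_log: list[dict] = []
        self.masses = np.array([MASSES.get(a.element, 14.0)
                                for _, a in model.atoms()])
        flat = model.atom_list()
        if mobile_keys is None:
            self.mobile = np.ones(len(flat), dtype=bool)
        else:
            keys = {tuple(k) for k in mobile_keys}
            self.mobile = np.array([r.key in keys for r, _ in flat])

    # -- setup -------------------------------------------------------------
    def add_provider(self, provider: ForceProvider) -> None:
        self.providers.append(provider)

    def use_default_providers(self, map_potential: DensityMapPotential | None = None):
        self.add_provider(SimplifiedForceField(self.model))
        self.add_provider(RestraintForces(self))
        if map_potential is not None:
            self.add_provider(MapForces(map_potential, self.model))
        return self

    def mobile_residue_keys(self) -> set:
        flat = self.model.atom_list()
        return {r.key for (r, _), m in zip(flat, self.mobile) if m}

    @property
    def signature(self) -> tuple:
        flat = self.model.atom_list()
        return (len(flat), flat[0][0].key + (flat[0][1].name,),
                flat[-1][0].key + (flat[-1][1].name,))

    # -- energy/forces -----------------------------------------------------
    def energy_breakdown(self, positions=None) -> dict[str, float]:
        pos = self.positions if positions is None else positions
        return {p.name: p.evaluate(pos)[0] for p in self.providers}

    def compute(self, positions=None) -> tuple[float, np.ndarray]:
        pos = self.positions if positions is None else positions
        e = 0.0
        forces = np.zeros_like(pos)
        for p in self.providers:
            ep, fp = p.evaluate(pos)
            e += ep
            forces += fp
        if not np.isfinite(e) or not np.all(np.isfinite(forces)):
            i, j, d = self._worst_pair(pos)
            raise SimulationError(
                f"non-finite energy; worst atom pair {i} - {j} at {d:.3f} A")
        forces[~self.mobile] = 0.0
        return e, forces

    def _worst_pair(self, pos):
        from scipy.spatial import cKDTree

        tree = cKDTree(pos)
        d, idx = tree.query(pos, k=2)
        w = int(np.argmin(d[:, 1]))
        flat = self.model.atom_list()

        def label(i):
            r, a = flat[i]
            return f"{r.chain_id}/{r.name}{r.seq_number}/{a.name}"

        return label(w), label(int(idx[w, 1])), float(d[w, 1])

    def kinetic_energy(self) -> float:
        v2 = np.sum(self.velocities ** 2, axis=1)
        return 0.5 * float(np.sum(self.masses * v2)) / FORCE_TO_ACC

    def write_back(self) -> StructureModel:
        """Copy working positions into the model and return it."""
        self.model.set_positions(self.positions)
        return self.model

    # -- coordinate-update housekeeping -------------------------------------
    def _coordinate_update(self) -> None:
        self.frame += 1
        for updater in list(self.moving_updaters):
            updater(self)
        self.restraints.check_temporaries(self._current_model(), self.frame)
        if self.validation_cadence and self.frame % self.validation_cadence == 0:
            m = self._current_model()
            _, omega_counts = validation.peptide_bond_report(m)
            _, rama = validation.rama_report(m)
            entry = {"frame": self.frame,
                     "cis_nonproline": omega_counts["cis_nonproline"],
                     "twisted": omega_counts["twisted"],
                     "rama_outlier_percent": rama["outlier_percent"]}
            self.validation_log.append(entry)
            log.debug("frame %d: %s", self.frame, entry)

    def _current_model(self) -> StructureModel:
        m = self.model.copy()
        m.set_positions(self.positions)
        return m

    def run(self, n_steps: int) -> "SimulationState":
        return langevin_step(self, n_steps)


# ---------------------------------------------------------------------------
# integrators
# ---------------------------------------------------------------------------

def langevin_step(state: SimulationState, n_steps: int) -> SimulationState:
    """BAOAB Langevin integration; at T = 0 this is damped settling.

    Fixed atoms are pinned.  Every coordinate update (20 steps) the moving
    restraints advance and temporary restraints are checked; validation
    refreshes every ten coordinate updates.  Raises on unstable steps
    (> 1 A displacement in one timestep).
    """
    dt = state.timestep
    gamma = state.friction
    c1 = math.exp(-gamma * dt)
    kT = KB * state.temperature
    m = state.masses[:, None]
    sigma_v = math.sqrt(kT * FORCE_TO_ACC) * np.sqrt(1.0 - c1 * c1) / np.sqrt(m)
    mobile = state.mobile
    _, forces = state.compute()
    for _ in range(n_steps):
        acc = forces * FORCE_TO_ACC / m
        state.velocities += 0.5 * dt * acc
        dx1 = 0.5 * dt * state.velocities
        noise = state.rng.standard_normal(state.positions.shape)
        state.velocities = c1 * state.velocities + sigma_v * noise
        state.velocities[~mobile] = 0.0
        dx2 = 0.5 * dt * state.velocities
        dx = dx1 + dx2
        dx[~mobile] = 0.0
        if np.max(np.abs(dx)) > 1.0:
            i = int(np.argmax(np.max(np.abs(dx), axis=1)))
            raise SimulationError(
                f"unstable step: atom {i} moved {np.max(np.abs(dx)):.2f} A "
                "in one timestep")
        state.positions += dx
        _, forces = state.compute()
        state.velocities += 0.5 * dt * forces * FORCE_TO_ACC / m
        state.velocities[~mobile] = 0.0
        state.step_count += 1
        if state.step_count % state.coordinate_update_interval == 0:
            state._coordinate_update()
            _, forces = state.compute()
    return state


def minimize(state: SimulationState, max_steps: int = 500,
             force_tol: float = 10.0) -> SimulationState:
    """L-BFGS energy minimization of the mobile atoms.

    Stops when the maximum per-atom force drops below ``force_tol``
    (kJ/mol/A) or after ``max_steps`` iterations.  The energy trace over
    accepted iterates is non-increasing and is stored on
    ``state.minimization_trace``.
    """
    from scipy.optimize import minimize as _scipy_min

    mobile = np.nonzero(state.mobile)[0]
    e0, f0 = state.compute()
    trace = [e0]
    state.minimization_trace = trace
    if len(mobile) == 0 or np.max(np.linalg.norm(f0[mobile], axis=1)) <= force_tol:
        return state

    x_full = state.positions.copy()

    def fun(x):
        pos = x_full.copy()
        pos[mobile] = x.reshape(-1, 3)
        e, f = state.compute(pos)
        return e, -f[mobile].ravel()

    class _Done(Exception):
        pass

    def cb(xk):
        pos = x_full.copy()
        pos[mobile] = xk.reshape(-1, 3)
        e, f = state.compute(pos)
        trace.append(e)
        if np.max(np.linalg.norm(f[mobile], axis=1)) <= force_tol:
            best["x"] = xk
            raise _Done

    best = {"x": None}
    try:
        res = _scipy_min(fun, state.positions[mobile].ravel(), jac=True,
                         method="L-BFGS-B", callback=cb,
                         options={"maxiter": max_steps, "ftol": 1e-12,
                                  "gtol": 1e-10})
        xk = res.x
    except _Done:
        xk = best["x"]
    state.positions[mobile] = xk.reshape(-1, 3)
    return state


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(state: SimulationState) -> Checkpoint:
    """Snapshot positions and all custom restraints; any number may be kept."""
    return Checkpoint(positions=state.positions.copy(),
                      velocities=state.velocities.copy(),
                      restraints=state.restraints.copy(),
                      frame=state.frame,
                      signature=state.signature)


def restore_checkpoint(state: SimulationState, cp: Checkpoint) -> SimulationState:
    """Return to a checkpoint, discarding all subsequent changes."""
    if cp.signature != state.signature:
        raise SimulationError("checkpoint belongs to a different model topology")
    state.positions = cp.positions.copy()
    state.velocities = cp.velocities.copy()
    state.restraints = cp.restraints.copy()
    state.frame = cp.frame
    return state


# ---------------------------------------------------------------------------
# the settle pipeline
# ---------------------------------------------------------------------------

def settle_model(model: StructureModel,
                 density_map=None,
                 selection=None,
                 map_weight: float = 20.0,
                 temperature: float = DEFAULT_TEMPERATURE,
                 md_steps: int = 600,
                 minimize_max_steps: int = 500,
                 force_tol: float = 20.0,
                 seed: int = 0,
                 restrain_omega: bool = True,
                 validate: bool = True,
                 ) -> tuple[StructureModel, dict]:
    """Non-interactive settle: minimize, Langevin at T, re-minimize at 0 K.

    ``selection`` defaults to the entire structure (the recommended first
    run on a new model, to resolve bad clashes); otherwise it is expanded
    into mobile + fixed-shell sets.  ``density_map`` may be a
    :class:`DensityMap` (coupled at ``map_weight``) or an existing
    :class:`DensityMapPotential`.  Returns the settled model copy and a
    report with before/after validation summaries.
    """
    from .map_potential import DensityMap
    from .restraints import add_default_omega_restraints
    from .structure import expand_selection

    work = model.copy()
    if selection is None:
        mobile_keys = None
    else:
        mobile_keys, _shell = expand_selection(work, selection)
    rset = RestraintSet()
    if restrain_omega:
        add_default_omega_restraints(rset, work)
    potential = None
    if density_map is not None:
        potential = (density_map if isinstance(density_map, DensityMapPotential)
                     else DensityMapPotential(density_map, weight=map_weight))
    state = SimulationState(work, restraints=rset, mobile_keys=mobile_keys,
                            temperature=temperature, seed=seed)
    state.use_default_providers(potential)
    if not validate:
        state.validation_cadence = 0

    report: dict = {}
    if validate:
        _, report["omega_before"] = validation.peptide_bond_report(model)
        _, report["rama_before"] = validation.rama_report(model)
    e_start = state.compute()[0]
    minimize(state, max_steps=minimize_max_steps, force_tol=force_tol)
    if md_steps > 0:
        langevin_step(state, md_steps)
    state.temperature = 0.0
    minimize(state, max_steps=minimize_max_steps, force_tol=force_tol)
    e_end = state.compute()[0]
    out = state.write_back()
    if validate:
        _, report["omega_after"] = validation.peptide_bond_report(out)
        _, report["rama_after"] = validation.rama_report(out)
    report["energy_initial"] = e_start
    report["energy_final"] = e_end
    report["validation_log"] = state.validation_log
    return out, report
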