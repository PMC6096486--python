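"""Macromolecular model container, measurement and synthetic-peptide fixtures.

Coordinates are in angstroms throughout, angles in degrees in (-180, 180],
and residues carry author (PDB-style, 1-based) numbering.  File I/O goes
through :mod:`gemmi`; ideal residue geometry for the fixture builder comes
from the Chemical Component Dictionary bundled with :mod:`biotite`.
"""
from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

log = logging.getLogger("flexfit")

# Consecutive residues are considered peptide-bonded iff the C(i)-N(i+1)
# distance is below this cutoff; chain breaks therefore yield no omega.
PEPTIDE_BOND_CUTOFF = 1.8

BACKBONE_NAMES = ("N", "CA", "C", "O", "OXT")

#: canonical (phi, psi) used by the fixture builder, degrees
CANONICAL_PHI_PSI = {
    "alpha": (-57.0, -47.0),
    "beta": (-119.0, 113.0),
    "extended": (180.0, 180.0),
}

# Ideal backbone internal coordinates (angstrom / degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_O_C_N = 123.0

AA_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA_ONE = {v: k for k, v in AA_THREE.items()}

#: side-chain chi dihedral definitions (atom name quadruples), standard
CHI_ATOMS = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

RECOGNIZED_ELEMENTS = {
    "H", "D", "C", "N", "O", "S", "P", "SE", "F", "CL", "BR", "I",
    "NA", "K", "MG", "CA", "MN", "FE", "CO", "NI", "CU", "ZN", "X",
}


class FlexfitError(Exception):
    """Base class for all errors raised by this package."""


class StructureParseError(FlexfitError):
    pass


class StructureFormatError(FlexfitError):
    pass


class DihedralError(FlexfitError):
    pass


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise FlexfitError(f"atom {self.name}: position must be a finite 3-vector")
        el = self.element.upper()
        if el not in RECOGNIZED_ELEMENTS:
            raise FlexfitError(f"atom {self.name}: unrecognized element {self.element!r}")
        self.element = el

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    insertion_code: str
    name: str
    atoms: list[Atom] = field(default_factory=list)
    secondary_structure: str = "unassigned"
    het: bool = False

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def is_amino_acid(self) -> bool:
        return self.name in AA_ONE

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms if not a.is_hydrogen])


@dataclass
class DihedralRecord:
    residue: Residue
    kind: str  # phi | psi | omega | chi1..chi4
    atoms: tuple[Atom, Atom, Atom, Atom]
    angle: float

    def recompute(self) -> float:
        return measure_dihedral(*(a.position for a in self.atoms))


class StructureModel:
    """Ordered chains of ordered residues.

    Residue order within a chain follows file order; peptide bonds are
    detected geometrically (C-N < 1.8 A), so numbering gaps with continuous
    geometry still bond and numbering continuity across a physical break
    does not.
    """

    def __init__(self, title: str = ""):
        self.title = title
        self.chains: dict[str, list[Residue]] = {}
        self._index: dict[tuple, int] | None = None

    # -- construction -----------------------------------------------------
    def add_residue(self, residue: Residue) -> None:
        self.chains.setdefault(residue.chain_id, []).append(residue)
        self._index = None

    # -- iteration --------------------------------------------------------
    def residues(self) -> Iterator[Residue]:
        for chain in self.chains.values():
            yield from chain

    def amino_residues(self) -> Iterator[Residue]:
        for r in self.residues():
            if r.is_amino_acid:
                yield r

    def atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for r in self.residues():
            for a in r.atoms:
                yield r, a

    def __len__(self) -> int:
        return sum(len(c) for c in self.chains.values())

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def residue(self, key: tuple[str, int, str] | tuple[str, int]) -> Residue:
        chain_id, seq = key[0], key[1]
        icode = key[2] if len(key) > 2 else ""
        for r in self.chains.get(chain_id, []):
            if r.seq_number == seq and r.insertion_code == icode:
                return r
        raise KeyError(f"no residue {key} in model")

    # -- flat coordinate access (used by the dynamics engine) -------------
    def atom_list(self) -> list[tuple[Residue, Atom]]:
        return list(self.atoms())

    def atom_index(self) -> dict[tuple, int]:
        """Map (chain_id, seq, icode, atom_name) -> flat atom index."""
        if self._index is None:
            self._index = {
                r.key + (a.name,): i for i, (r, a) in enumerate(self.atoms())
            }
        return self._index

    def positions(self) -> np.ndarray:
        return np.array([a.position for _, a in self.atoms()], dtype=float)

    def set_positions(self, pos: np.ndarray) -> None:
        pos = np.asarray(pos, dtype=float)
        if pos.shape != (self.n_atoms, 3):
            raise FlexfitError("position array shape does not match model")
        for (r, a), p in zip(self.atoms(), pos):
            a.position = p.copy()

    def copy(self) -> "StructureModel":
        return copy.deepcopy(self)

    # -- connectivity ------------------------------------------------------
    def bonded_pairs(self, chain_id: str) -> list[tuple[int, int]]:
        """Indices (within the chain list) of peptide-bonded residue pairs."""
        out = []
        chain = self.chains[chain_id]
        for i in range(len(chain) - 1):
            if residues_bonded(chain[i], chain[i + 1]):
                out.append((i, i + 1))
        return out


def residues_bonded(r1: Residue, r2: Residue) -> bool:
    c = r1.atom("C")
    n = r2.atom("N")
    if c is None or n is None:
        return False
    return float(np.linalg.norm(c.position - n.position)) < PEPTIDE_BOND_CUTOFF


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def wrap_angle(angle) -> float | np.ndarray:
    """Wrap degrees into (-180, 180]."""
    a = -((-np.asarray(angle) + 180.0) % 360.0 - 180.0)
    return float(a) if np.ndim(angle) == 0 else a


def measure_dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle in degrees, IUPAC sign convention.

    Looking from p2 toward p3, a clockwise rotation of the far bond
    relative to the near bond is positive.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    for a, b in ((p1, p2), (p2, p3), (p3, p4)):
        if np.linalg.norm(b - a) < 1e-10:
            raise DihedralError("coincident consecutive points")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DihedralError("colinear points: dihedral undefined")
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    ang = math.degrees(math.atan2(y, x))
    return wrap_angle(ang)


def backbone_dihedrals(model: StructureModel) -> list[DihedralRecord]:
    """One phi, psi and omega record per amino-acid residue where defined.

    Chain termini and chain breaks simply yield no record; residues with
    missing defining atoms are skipped with a logged note.
    """
    records: list[DihedralRecord] = []
    for chain_id, chain in model.chains.items():
        aa = [r for r in chain if r.is_amino_acid]
        for i, res in enumerate(aa):
            prev = aa[i - 1] if i > 0 else None
            nxt = aa[i + 1] if i + 1 < len(aa) else None
            if prev is not None and not residues_bonded(prev, res):
                prev = None
            if nxt is not None and not residues_bonded(res, nxt):
                nxt = None
            n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
            if None in (n, ca, c):
                log.debug("residue %s missing backbone atoms; dihedrals skipped",
                          res.key)
                continue
            if prev is not None:
                pca, pc = prev.atom("CA"), prev.atom("C")
                if pca is not None and pc is not None:
                    try:
                        records.append(DihedralRecord(
                            res, "omega", (pca, pc, n, ca),
                            measure_dihedral(pca.position, pc.position,
                                             n.position, ca.position)))
                        records.append(DihedralRecord(
                            res, "phi", (pc, n, ca, c),
                            measure_dihedral(pc.position, n.position,
                                             ca.position, c.position)))
                    except DihedralError:
                        log.debug("degenerate dihedral at %s", res.key)
            if nxt is not None:
                nn = nxt.atom("N")
                if nn is not None:
                    try:
                        records.append(DihedralRecord(
                            res, "psi", (n, ca, c, nn),
                            measure_dihedral(n.position, ca.position,
                                             c.position, nn.position)))
                    except DihedralError:
                        log.debug("degenerate psi at %s", res.key)
    return records


def chi_dihedrals(residue: Residue) -> list[DihedralRecord]:
    """chi1..chi4 records for a residue, where the defining atoms exist."""
    records = []
    for i, quad in enumerate(CHI_ATOMS.get(residue.name, [])):
        atoms = tuple(residue.atom(n) for n in quad)
        if any(a is None for a in atoms):
            continue
        records.append(DihedralRecord(
            residue, f"chi{i + 1}", atoms,
            measure_dihedral(*(a.position for a in atoms))))
    return records


def dihedral_record(model: StructureModel, residue: Residue,
                    kind: str) -> DihedralRecord | None:
    if kind.startswith("chi"):
        for rec in chi_dihedrals(residue):
            if rec.kind == kind:
                return rec
        return None
    for rec in backbone_dihedrals(model):
        if rec.residue is residue and rec.kind == kind:
            return rec
    return None


# ---------------------------------------------------------------------------
# file I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def _detect_format(path: str, fmt: str) -> str:
    if fmt != "auto":
        if fmt not in ("pdb", "mmcif"):
            raise StructureFormatError(f"unknown structure format {fmt!r}")
        return fmt
    p = str(path).lower()
    if p.endswith((".cif", ".mmcif", ".cif.gz")):
        return "mmcif"
    return "pdb"


def read_structure(path: str, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties keep the first encountered); dropped altlocs are logged.
    Secondary structure is taken from HELIX/SHEET records (or the mmCIF
    equivalents) when present and is never computed.
    """
    import gemmi

    fmt = _detect_format(path, format)
    try:
        st = gemmi.read_structure(
            str(path),
            format=gemmi.CoorFormat.Pdb if fmt == "pdb" else gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureParseError(f"cannot parse {path} as {fmt}: {exc}") from exc
    if len(st) == 0 or st[0].count_atom_sites() == 0:
        raise StructureParseError(f"{path}: no atoms found")

    model = StructureModel(title=st.name)
    gmodel = st[0]
    for chain in gmodel:
        for gres in chain:
            res = Residue(
                chain_id=chain.name,
                seq_number=gres.seqid.num,
                insertion_code=gres.seqid.icode.strip(),
                name=gres.name,
                het=gres.het_flag == "H",
            )
            # resolve altlocs: group by atom name, keep max occupancy
            by_name: dict[str, list] = {}
            for ga in gres:
                by_name.setdefault(ga.name, []).append(ga)
            for name, group in by_name.items():
                best = max(group, key=lambda a: a.occ)
                if len(group) > 1:
                    log.info("dropped %d altloc(s) of %s/%s %s",
                             len(group) - 1, chain.name, gres.seqid.num, name)
                el = best.element.name.upper() or "X"
                if el not in RECOGNIZED_ELEMENTS:
                    el = "X"
                res.atoms.append(Atom(
                    name=name, element=el,
                    position=np.array([best.pos.x, best.pos.y, best.pos.z]),
                    occupancy=best.occ, b_factor=best.b_iso))
            model.add_residue(res)

    _apply_secondary_structure(model, st)
    return model


def _apply_secondary_structure(model: StructureModel, st) -> None:
    for helix in st.helices:
        _mark_ss(model, helix.start, helix.end, "helix")
    for sheet in st.sheets:
        for strand in sheet.strands:
            _mark_ss(model, strand.start, strand.end, "strand")


def _mark_ss(model, start, end, kind) -> None:
    chain = model.chains.get(start.chain_name)
    if not chain:
        return
    marking = False
    for res in chain:
        if (res.seq_number == start.res_id.seqid.num
                and res.insertion_code == start.res_id.seqid.icode.strip()):
            marking = True
        if marking:
            res.secondary_structure = kind
        if (res.seq_number == end.res_id.seqid.num
                and res.insertion_code == end.res_id.seqid.icode.strip()):
            break


def write_structure(model: StructureModel, path: str, format: str = "auto") -> None:
    """Write a model as PDB or mmCIF (round-trips with :func:`read_structure`)."""
    import gemmi

    if len(model) == 0:
        raise FlexfitError("cannot write an empty model")
    fmt = _detect_format(path, format)
    st = gemmi.Structure()
    st.name = model.title or "flexfit model"
    gmodel = gemmi.Model("1")
    serial = 1
    for chain_id, chain in model.chains.items():
        gchain = gemmi.Chain(chain_id)
        for res in chain:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_number, res.insertion_code or " ")
            gres.het_flag = "H" if res.het else "A"
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element.capitalize())
                ga.pos = gemmi.Position(*a.position)
                ga.occ = a.occupancy
                ga.b_iso = a.b_factor
                ga.serial = serial
                serial += 1
                gres.add_atom(ga)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    try:
        if fmt == "pdb":
            st.write_pdb(str(path))
        else:
            st.make_mmcif_document().write_file(str(path))
    except (RuntimeError, OSError) as exc:
        raise FlexfitError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# selection expansion
# ---------------------------------------------------------------------------

def expand_selection(model: StructureModel,
                     seed: Iterable,
                     n_along: int = 3,
                     radius: float = 5.0,
                     shell_radius: float | None = None,
                     ) -> tuple[set, set]:
    """Expand a seed residue selection into (mobile, fixed_shell) key sets.

    The seed is grown by ``n_along`` residues in each direction along each
    chain, then by all residues having any heavy atom within ``radius`` of
    the grown set.  The fixed shell is every remaining residue with a heavy
    atom within ``shell_radius`` (default: same as ``radius``) of the mobile
    set.
    """
    from scipy.spatial import cKDTree

    seed_keys = set()
    for s in seed:
        res = s if isinstance(s, Residue) else model.residue(s)
        seed_keys.add(res.key)
    if not seed_keys:
        raise FlexfitError("empty seed selection")
    if shell_radius is None:
        shell_radius = radius

    # grow along each chain
    grown = set(seed_keys)
    for chain_id, chain in model.chains.items():
        idx = [i for i, r in enumerate(chain) if r.key in seed_keys]
        for i in idx:
            lo, hi = max(0, i - n_along), min(len(chain), i + n_along + 1)
            grown.update(chain[j].key for j in range(lo, hi))

    def _coords(keys):
        pts, owner = [], []
        for r in model.residues():
            if r.key in keys:
                for a in r.heavy_atoms():
                    pts.append(a.position)
        return np.array(pts) if pts else np.zeros((0, 3))

    grown_pts = _coords(grown)
    tree = cKDTree(grown_pts)
    mobile = set(grown)
    for r in model.residues():
        if r.key in mobile:
            continue
        pts = r.heavy_coords()
        if len(pts) and np.any(tree.query(pts)[0] <= radius):
            mobile.add(r.key)

    mobile_pts = _coords(mobile)
    mtree = cKDTree(mobile_pts)
    shell = set()
    for r in model.residues():
        if r.key in mobile:
            continue
        pts = r.heavy_coords()
        if len(pts) and np.any(mtree.query(pts)[0] <= shell_radius):
            shell.add(r.key)
    return mobile, shell


# ---------------------------------------------------------------------------
# ideal peptide builder
# ---------------------------------------------------------------------------

def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d bonded to c with angle b-c-d and torsion a-b-c-d (NeRF)."""
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * math.cos(ang),
                   bond * math.sin(ang) * math.cos(tor),
                   bond * math.sin(ang) * math.sin(tor)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _ccd_heavy(resname: str):
    """Heavy-atom names, coordinates and bonds from the bundled CCD."""
    import biotite.structure.info as info

    try:
        arr = info.residue(resname)
    except KeyError as exc:
        raise FlexfitError(f"unknown residue type {resname!r}") from exc
    if arr is None:
        raise FlexfitError(f"unknown residue type {resname!r}")
    heavy = arr[(arr.element != "H") & (arr.atom_name != "OXT")]
    bonds = []
    idx_of = {n: i for i, n in enumerate(heavy.atom_name)}
    pairs, _ = arr.bonds.get_all_bonds()
    names = arr.atom_name
    seen = set()
    for i in range(arr.array_length()):
        for j in pairs[i]:
            if j < 0:
                continue
            a, b = names[i], names[j]
            if a in idx_of and b in idx_of and (b, a) not in seen:
                seen.add((a, b))
                bonds.append((a, b))
    return heavy.atom_name.tolist(), heavy.coord.astype(float), heavy.element.tolist(), bonds


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation R and translation t with R @ p + t ~ q for paired points."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, qc - R @ pc


def build_ideal_peptide(sequence: str,
                        conformation: str = "alpha",
                        chain_id: str = "A") -> StructureModel:
    """Build an ideal polypeptide with canonical backbone torsions.

    All omega angles are 180 deg (trans); phi/psi take the canonical values
    for ``conformation``.  Heavy atoms only; side chains are grafted from
    ideal component geometry, so bond lengths and angles are ideal.
    """
    if not sequence:
        raise FlexfitError("empty sequence")
    if conformation not in CANONICAL_PHI_PSI:
        raise FlexfitError(f"unknown conformation {conformation!r}")
    for ch in sequence:
        if ch not in AA_THREE:
            raise FlexfitError(f"unknown residue letter {ch!r}")
    phi0, psi0 = CANONICAL_PHI_PSI[conformation]

    n = len(sequence)
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    # first residue backbone in a canonical frame
    N[0] = np.array([0.0, 0.0, 0.0])
    CA[0] = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    for i in range(n - 1):
        N[i + 1] = place_atom(N[i], CA[i], C[i], BOND_C_N, ANGLE_CA_C_N, psi0)
        CA[i + 1] = place_atom(CA[i], C[i], N[i + 1], BOND_N_CA, ANGLE_C_N_CA, 180.0)
        C[i + 1] = place_atom(C[i], N[i + 1], CA[i + 1], BOND_CA_C, ANGLE_N_CA_C, phi0)

    model = StructureModel(title=f"ideal {conformation} peptide {sequence}")
    for i, letter in enumerate(sequence):
        resname = AA_THREE[letter]
        res = Residue(chain_id=chain_id, seq_number=i + 1, insertion_code="",
                      name=resname)
        res.atoms.append(Atom("N", "N", N[i]))
        res.atoms.append(Atom("CA", "C", CA[i]))
        res.atoms.append(Atom("C", "C", C[i]))
        o = place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O,
                       wrap_angle(psi0 + 180.0))
        res.atoms.append(Atom("O", "O", o))
        # graft side chain from ideal component geometry
        names, coords, elements, _ = _ccd_heavy(resname)
        ref = {nm: coords[j] for j, nm in enumerate(names)}
        P = np.array([ref["N"], ref["CA"], ref["C"]])
        Q = np.array([N[i], CA[i], C[i]])
        R, _ = _kabsch(P, Q)
        # anchor exactly at CA so CA-CB keeps its ideal length
        t = CA[i] - R @ ref["CA"]
        for j, nm in enumerate(names):
            if nm in ("N", "CA", "C", "O"):
                continue
            res.atoms.append(Atom(nm, elements[j], R @ coords[j] + t))
        model.add_residue(res)
    return model
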