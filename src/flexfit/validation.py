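"""Backbone geometry validation and model-vs-model change analysis.

Omega classification follows the convention that a peptide bond is cis for
|omega| <= 30 deg, trans for |omega| >= 150 deg and twisted in between;
ultrahigh-resolution surveys show twists beyond 30 deg to be vanishingly
rare, which is what makes twisted and cis-nonproline bonds strong error
signals.

Ramachandran scoring assigns each residue to one of six cases (general,
glycine, cis-proline, trans-proline, pre-proline, Ile/Val) and reports a
probability score P in percent with the conventional class boundaries:
outlier P < 0.05, marginal 0.05 <= P < 2, favoured P >= 2.

The bundled reference distributions are SYNTHETIC: smooth parametric
(wrapped-Gaussian mixture) stand-ins for empirically derived contour
tables, constructed so that the canonical favoured basins (alpha, beta,
left-handed alpha) and disallowed regions behave correctly.  Absolute
outlier percentages on real structures will differ from scores computed
with empirical reference data.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .structure import (
    FlexfitError, Residue, StructureModel, backbone_dihedrals, wrap_angle,
)

log = logging.getLogger("flexfit")

CIS_MAX = 30.0        # deg: cis iff |omega| <= CIS_MAX
TRANS_MIN = 150.0     # deg: trans iff |omega| >= TRANS_MIN
OUTLIER_P = 0.05      # percent
FAVOURED_P = 2.0      # percent

DIHEDRAL_CHANGE_CUTOFF = 45.0   # deg, model comparison
RMSD_CHANGE_CUTOFF = 2.0        # A, model comparison

COLOUR_MAROON = (0.55, 0.0, 0.0)
COLOUR_YELLOW = (1.0, 1.0, 0.0)
COLOUR_GREEN = (0.0, 0.8, 0.0)

RAMA_CASES = ("general", "glycine", "cis_proline", "trans_proline",
              "pre_proline", "ile_val")

_GRID_STEP = 2.0  # deg


# ---------------------------------------------------------------------------
# omega (peptide-bond) classification
# ---------------------------------------------------------------------------

def classify_omega(omega: float) -> str:
    """Partition (-180, 180] into cis / twisted / trans."""
    if not np.isfinite(omega):
        raise FlexfitError("omega must be finite")
    a = abs(wrap_angle(omega))
    if a <= CIS_MAX:
        return "cis"
    if a >= TRANS_MIN:
        return "trans"
    return "twisted"


@dataclass
class OmegaClass:
    residue: Residue
    omega: float
    omega_class: str
    proline: bool


def peptide_bond_report(model: StructureModel
                        ) -> tuple[list[OmegaClass], dict]:
    """All non-trans peptide bonds, with cis split into Pro and non-Pro.

    The bond belongs to the residue contributing its N (so a cis bond
    preceding a proline counts as cis-proline).
    """
    entries = []
    counts = {"cis_proline": 0, "cis_nonproline": 0, "twisted": 0,
              "trans": 0, "n_peptide_bonds": 0}
    for rec in backbone_dihedrals(model):
        if rec.kind != "omega":
            continue
        counts["n_peptide_bonds"] += 1
        cls = classify_omega(rec.angle)
        pro = rec.residue.name == "PRO"
        if cls == "trans":
            counts["trans"] += 1
            continue
        if cls == "cis":
            counts["cis_proline" if pro else "cis_nonproline"] += 1
        else:
            counts["twisted"] += 1
        entries.append(OmegaClass(rec.residue, rec.angle, cls, pro))
    return entries, counts


# ---------------------------------------------------------------------------
# Ramachandran reference distributions (synthetic)
# ---------------------------------------------------------------------------

def _wrapped_gaussian_2d(phi, psi, centre, sigma):
    d = 0.0
    for ofp in (-360.0, 0.0, 360.0):
        for ofs in (-360.0, 0.0, 360.0):
            dp = (phi - centre[0] + ofp) / sigma[0]
            ds = (psi - centre[1] + ofs) / sigma[1]
            d = d + np.exp(-0.5 * (dp * dp + ds * ds))
    return d / (2 * np.pi * sigma[0] * sigma[1])


# (centre_phi, centre_psi, sigma_phi, sigma_psi, weight) per case; the
# uniform floor weight makes the empty regions score just under the
# outlier boundary rather than exactly zero.
_RAMA_COMPONENTS = {
    "general": ([(-63, -43, 13, 13, 0.42), (-120, 135, 25, 28, 0.38),
                 (-63, 140, 18, 20, 0.10), (57, 42, 10, 11, 0.06),
                 (-100, -20, 25, 25, 0.04)], 2e-4),
    "glycine": ([(-63, -43, 14, 14, 0.22), (63, 43, 14, 14, 0.22),
                 (-90, 170, 25, 25, 0.18), (90, -170, 25, 25, 0.18),
                 (-170, 175, 25, 22, 0.10), (170, -175, 25, 22, 0.10)], 1e-3),
    "trans_proline": ([(-63, -35, 9, 13, 0.45), (-63, 150, 9, 16, 0.45),
                       (-63, -10, 12, 18, 0.10)], 2e-4),
    "cis_proline": ([(-75, 155, 10, 14, 0.65), (-75, -15, 10, 16, 0.35)], 2e-4),
    "pre_proline": ([(-63, -40, 12, 13, 0.30), (-120, 130, 22, 25, 0.50),
                     (-63, 140, 15, 18, 0.12), (55, 40, 9, 10, 0.08)], 2e-4),
    "ile_val": ([(-63, -45, 10, 12, 0.45), (-115, 125, 18, 22, 0.50),
                 (57, 42, 8, 9, 0.05)], 2e-4),
}


@lru_cache(maxsize=None)
def _rama_grid(case: str) -> np.ndarray:
    """Percentile grid P (percent) on a 2-deg (phi, psi) lattice.

    P(phi, psi) = 100 * Pr[density(X) <= density(phi, psi)] for X drawn
    from the case's reference distribution, mirroring the contour-level
    semantics of the conventional outlier/favoured boundaries.
    """
    if case not in _RAMA_COMPONENTS:
        raise FlexfitError(f"unknown Ramachandran case {case!r}")
    comps, floor_mass = _RAMA_COMPONENTS[case]
    ax = np.arange(-180.0, 180.0, _GRID_STEP)
    phi, psi = np.meshgrid(ax, ax, indexing="ij")
    dens = np.zeros_like(phi)
    for cp, cs, sp, ss, w in comps:
        dens += w * _wrapped_gaussian_2d(phi, psi, (cp, cs), (sp, ss))
    dens *= (1.0 - floor_mass) / (dens.sum() * _GRID_STEP ** 2)
    dens += floor_mass / (360.0 ** 2)
    mass = dens / dens.sum()
    order = np.argsort(dens, axis=None)
    cum = np.cumsum(mass.ravel()[order])
    p = np.empty(dens.size)
    p[order] = cum * 100.0
    return p.reshape(dens.shape)


def rama_probability(case: str, phi: float, psi: float) -> float:
    """Ramachandran probability score P in percent (bilinear lookup).

    Periodic in both angles with period 360 deg.
    """
    grid = _rama_grid(case)
    n = grid.shape[0]
    fi = (np.asarray(phi, dtype=float) + 180.0) / _GRID_STEP
    fj = (np.asarray(psi, dtype=float) + 180.0) / _GRID_STEP
    i0 = np.floor(fi).astype(int)
    j0 = np.floor(fj).astype(int)
    u, v = fi - i0, fj - j0
    i0, j0 = i0 % n, j0 % n
    i1, j1 = (i0 + 1) % n, (j0 + 1) % n
    val = (grid[i0, j0] * (1 - u) * (1 - v) + grid[i1, j0] * u * (1 - v)
           + grid[i0, j1] * (1 - u) * v + grid[i1, j1] * u * v)
    return float(val) if np.ndim(phi) == 0 else val


def rama_class(p: float) -> str:
    if p < OUTLIER_P:
        return "outlier"
    if p < FAVOURED_P:
        return "marginal"
    return "favoured"


def rama_colour(p: float) -> tuple[float, float, float]:
    """Maroon -> yellow -> green, varying with log10(P) between the class
    boundaries; P >= 2 is the pure-green endpoint."""
    if p <= OUTLIER_P:
        return COLOUR_MAROON
    if p >= FAVOURED_P:
        return COLOUR_GREEN
    lo, hi = np.log10(OUTLIER_P), np.log10(FAVOURED_P)
    x = (np.log10(p) - lo) / (hi - lo)  # 0..1 across the marginal band
    if x < 0.5:
        f = x / 0.5
        a, b = COLOUR_MAROON, COLOUR_YELLOW
    else:
        f = (x - 0.5) / 0.5
        a, b = COLOUR_YELLOW, COLOUR_GREEN
    return tuple((1 - f) * np.array(a) + f * np.array(b))


@dataclass
class RamaClass:
    residue: Residue
    phi: float
    psi: float
    case: str
    probability: float
    rama_class: str
    colour: tuple[float, float, float]


def _assign_case(res: Residue, next_res: Residue | None,
                 omega: float | None) -> str:
    if res.name == "PRO":
        if omega is not None and classify_omega(omega) == "cis":
            return "cis_proline"
        return "trans_proline"
    if res.name == "GLY":
        return "glycine"
    if next_res is not None and next_res.name == "PRO":
        return "pre_proline"
    if res.name in ("ILE", "VAL"):
        return "ile_val"
    return "general"


def rama_report(model: StructureModel) -> tuple[list[RamaClass], dict]:
    """Classify every residue with defined phi and psi; summarize fractions.

    Returns (entries, summary) where summary holds favoured/marginal/
    outlier percentages over the classified residues.
    """
    recs: dict[tuple, dict] = {}
    for rec in backbone_dihedrals(model):
        recs.setdefault(rec.residue.key, {"residue": rec.residue})[rec.kind] = rec.angle
    entries = []
    for chain in model.chains.values():
        aa = [r for r in chain if r.is_amino_acid]
        for i, res in enumerate(aa):
            d = recs.get(res.key)
            if d is None or "phi" not in d or "psi" not in d:
                continue
            nxt = aa[i + 1] if i + 1 < len(aa) else None
            case = _assign_case(res, nxt, d.get("omega"))
            p = rama_probability(case, d["phi"], d["psi"])
            entries.append(RamaClass(res, d["phi"], d["psi"], case, p,
                                     rama_class(p), rama_colour(p)))
    n = len(entries)
    summary = {"n_classified": n}
    for cls in ("favoured", "marginal", "outlier"):
        count = sum(1 for e in entries if e.rama_class == cls)
        summary[cls + "_percent"] = 100.0 * count / n if n else 0.0
    return entries, summary


# ---------------------------------------------------------------------------
# model-vs-model change analysis
# ---------------------------------------------------------------------------

def _kabsch_transform(P, Q):
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, qc - R @ pc


def compare_models(a: StructureModel, b: StructureModel,
                   dihedral_cutoff: float = DIHEDRAL_CHANGE_CUTOFF,
                   rmsd_cutoff: float = RMSD_CHANGE_CUTOFF,
                   superpose: bool = False) -> tuple[pd.DataFrame, dict]:
    """Per-residue backbone-torsion and position changes between two models.

    Residues are matched by (chain, seq number, insertion code).  RMSDs are
    over heavy atoms present in both, computed in the shared frame (the
    intended use is models refined against the same map); ``superpose``
    optionally applies a global CA superposition of b onto a first.
    A residue is flagged ``dihedral_changed`` if any of |d phi|, |d psi| or
    |d omega| exceeds ``dihedral_cutoff`` and ``moved`` if its RMSD exceeds
    ``rmsd_cutoff``; ``combined`` is their union.
    """
    def _dihedral_table(m):
        out = {}
        for rec in backbone_dihedrals(m):
            out.setdefault(rec.residue.key, {})[rec.kind] = rec.angle
        return out

    res_a = {r.key: r for r in a.amino_residues()}
    res_b = {r.key: r for r in b.amino_residues()}
    matched = [k for k in res_a if k in res_b]
    if not matched:
        raise FlexfitError("no residues matched between the two models")
    unmatched = sorted(set(res_a) ^ set(res_b))
    if unmatched:
        log.info("%d residue(s) present in only one model", len(unmatched))

    b_shift = None
    if superpose:
        pa = np.array([res_a[k].atom("CA").position for k in matched
                       if res_a[k].atom("CA") and res_b[k].atom("CA")])
        pb = np.array([res_b[k].atom("CA").position for k in matched
                       if res_a[k].atom("CA") and res_b[k].atom("CA")])
        R, t = _kabsch_transform(pb, pa)
        b_shift = (R, t)

    da, db = _dihedral_table(a), _dihedral_table(b)
    rows = []
    for key in matched:
        ra, rb = res_a[key], res_b[key]
        deltas = {}
        for kind in ("phi", "psi", "omega"):
            va = da.get(key, {}).get(kind)
            vb = db.get(key, {}).get(kind)
            deltas[kind] = (abs(wrap_angle(vb - va))
                            if va is not None and vb is not None else np.nan)
        shared = [n for n in (at.name for at in ra.heavy_atoms())
                  if rb.atom(n) is not None]
        if shared:
            pa = np.array([ra.atom(n).position for n in shared])
            pb = np.array([rb.atom(n).position for n in shared])
            if b_shift is not None:
                R, t = b_shift
                pb = pb @ R.T + t
            rmsd = float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))
        else:
            rmsd = np.nan
        dihedral_changed = any(np.nan_to_num(deltas[k]) > dihedral_cutoff
                               for k in deltas)
        moved = bool(np.nan_to_num(rmsd) > rmsd_cutoff)
        rows.append({
            "chain": key[0], "seq": key[1], "icode": key[2],
            "name": ra.name,
            "d_phi": deltas["phi"], "d_psi": deltas["psi"],
            "d_omega": deltas["omega"], "rmsd": rmsd,
            "dihedral_changed": dihedral_changed, "moved": moved,
            "combined": dihedral_changed or moved,
        })
    table = pd.DataFrame(rows)

    phi_psi = np.concatenate([table["d_phi"].dropna().to_numpy(),
                              table["d_psi"].dropna().to_numpy()])
    omegas = table["d_omega"].dropna().to_numpy()
    summary = {
        "n_matched": len(table),
        "n_unmatched": len(unmatched),
        "phi_psi_changed_percent":
            100.0 * float((phi_psi > dihedral_cutoff).mean()) if len(phi_psi) else 0.0,
        "omega_changed_percent":
            100.0 * float((omegas > dihedral_cutoff).mean()) if len(omegas) else 0.0,
        "moved_percent": 100.0 * float(table["moved"].mean()),
        "dihedral_changed_percent": 100.0 * float(table["dihedral_changed"].mean()),
        "combined_percent": 100.0 * float(table["combined"].mean()),
    }
    return table, summary
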