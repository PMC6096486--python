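"""Deliberate error injection for end-to-end testing without downloads.

An :class:`ErrorRecipe` lists defects of the classes that dominate real
low-resolution rebuilding work — spurious cis peptide bonds, register
errors, scrambled rotamers, coordinate noise — and
:func:`inject_errors` applies them to a clean model, returning the
corrupted copy together with an answer key recording exactly what a
perfect rebuild (or validator) should find and where.

Defect semantics:

* ``cis_flip``: the omega torsion of the target residue is driven to 0 by
  an exact rigid rotation of everything downstream of the peptide C-N
  bond, so omega (and nothing else internal) changes;
* ``register_shift``: the run's backbone atoms are moved along fitted
  backbone splines to the sites of their neighbours n positions away
  (side chains ride along rigidly), i.e. the spline machinery run in
  reverse;
* ``rotamer_scramble``: chi1 is rotated by a fixed offset, swinging the
  side chain out of position;
* ``jitter``: seeded Gaussian noise on every heavy atom.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .register_shift import fit_backbone_splines
from .structure import (
    CHI_ATOMS, FlexfitError, Residue, StructureModel, measure_dihedral,
)

log = logging.getLogger("flexfit")


class FixtureError(FlexfitError):
    pass


@dataclass
class ErrorRecipe:
    """A reproducible list of defects to inject."""
    defects: list[dict] = field(default_factory=list)
    seed: int = 0

    def cis_flip(self, chain: str, seq: int):
        self.defects.append({"type": "cis_flip", "chain": chain, "seq": seq})
        return self

    def register_shift(self, chain: str, start: int, end: int, shift: int):
        self.defects.append({"type": "register_shift", "chain": chain,
                             "start": start, "end": end, "shift": int(shift)})
        return self

    def rotamer_scramble(self, chain: str, seq: int, offset: float = 120.0):
        self.defects.append({"type": "rotamer_scramble", "chain": chain,
                             "seq": seq, "offset": float(offset)})
        return self

    def jitter(self, sigma: float):
        self.defects.append({"type": "jitter", "sigma": float(sigma)})
        return self

    def to_json(self) -> str:
        return json.dumps({"seed": self.seed, "defects": self.defects}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ErrorRecipe":
        doc = json.loads(text)
        return cls(defects=doc.get("defects", []), seed=doc.get("seed", 0))

    def loci(self) -> list[set]:
        out = []
        for d in self.defects:
            if d["type"] == "cis_flip" or d["type"] == "rotamer_scramble":
                out.append({(d["chain"], d["seq"])})
            elif d["type"] == "register_shift":
                out.append({(d["chain"], s)
                            for s in range(d["start"], d["end"] + 1)})
            else:
                out.append(set())  # jitter is global, overlaps allowed
        return out


def _rotate_about_axis(points: np.ndarray, origin: np.ndarray,
                       axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    v = points - origin
    return (origin + v * np.cos(a)
            + np.cross(axis, v) * np.sin(a)
            + np.outer(v @ axis, axis) * (1 - np.cos(a)))


def _apply_cis_flip(model: StructureModel, chain_id: str, seq: int) -> dict:
    chain = [r for r in model.chains[chain_id] if r.is_amino_acid]
    res = model.residue((chain_id, seq, ""))
    i = chain.index(res)
    if i == 0:
        raise FixtureError(f"{chain_id}/{seq}: no peptide bond N-terminal to "
                           "a chain-leading residue")
    prev = chain[i - 1]
    pca, pc = prev.atom("CA").position, prev.atom("C").position
    n, ca = res.atom("N").position, res.atom("CA").position
    omega = measure_dihedral(pca, pc, n, ca)
    # rotate every atom downstream of the C-N bond (residues >= i, keeping
    # N on the axis) so omega becomes exactly 0
    movers = []
    for r in chain[i:]:
        for a in r.atoms:
            if r is res and a.name == "N":
                continue
            movers.append(a)
    pts = np.array([a.position for a in movers])
    pts = _rotate_about_axis(pts, pc, n - pc, -omega)
    for a, p in zip(movers, pts):
        a.position = p
    return {"type": "cis_flip", "residue": (chain_id, seq, ""),
            "expect": "cis peptide bond reported at this residue"}


def _apply_register_shift(model: StructureModel, chain_id: str, start: int,
                          end: int, shift: int) -> dict:
    chain = model.chains[chain_id]
    run = [r for r in chain if start <= r.seq_number <= end]
    if len(run) < 4:
        raise FixtureError("register-shift run must span >= 4 residues")
    # extend by |shift| where possible so moved residues have real targets
    keys = [r.key for r in chain]
    i0, i1 = keys.index(run[0].key), keys.index(run[-1].key)
    lo = max(0, i0 - (abs(shift) if shift < 0 else 0))
    hi = min(len(chain) - 1, i1 + (abs(shift) if shift > 0 else 0))
    fit_run = chain[lo:hi + 1]
    splines = fit_backbone_splines(model, [r.key for r in fit_run])
    offset = i0 - lo
    for j, r in enumerate(run):
        t = offset + j + shift
        ca_old = r.atom("CA").position.copy()
        for name in ("N", "C", "CA", "CB"):
            atom = r.atom(name)
            if atom is None or not splines.has(name):
                continue
            atom.position = splines.evaluate(name, t, clamp=True)
        delta = r.atom("CA").position - ca_old
        for atom in r.atoms:
            if atom.name not in ("N", "C", "CA", "CB"):
                atom.position = atom.position + delta
    return {"type": "register_shift", "chain": chain_id,
            "residues": [(chain_id, s, "") for s in range(start, end + 1)],
            "shift": shift,
            "expect": "run flagged as changed vs the original model; "
                      f"correctable by a register shift of {-shift}"}


def _apply_rotamer_scramble(model: StructureModel, chain_id: str, seq: int,
                            offset: float) -> dict:
    res = model.residue((chain_id, seq, ""))
    quads = CHI_ATOMS.get(res.name)
    if not quads:
        raise FixtureError(f"{res.name} has no chi dihedrals to scramble")
    a1, a2, a3, _ = quads[0]  # chi1: rotate about CA-CB (or equivalent)
    axis_from = res.atom(a2).position
    axis_to = res.atom(a3).position
    movers = [a for a in res.atoms
              if a.name not in ("N", "CA", "C", "O", "OXT", a2, a3)
              and not a.is_hydrogen and a.name != a1]
    pts = np.array([a.position for a in movers])
    pts = _rotate_about_axis(pts, axis_to, axis_to - axis_from, offset)
    for a, p in zip(movers, pts):
        a.position = p
    return {"type": "rotamer_scramble", "residue": (chain_id, seq, ""),
            "offset": offset,
            "expect": "residue flagged as moved vs the original model"}


def inject_errors(model: StructureModel, recipe: ErrorRecipe
                  ) -> tuple[StructureModel, list[dict]]:
    """Apply a recipe to a copy of ``model``; returns (corrupted, answer_key).

    Defect loci must not overlap (jitter is global and exempt); jitter is
    applied last with a generator seeded by ``recipe.seed`` so identical
    recipes corrupt identically.
    """
    loci = [l for l in recipe.loci() if l]
    for i, a in enumerate(loci):
        for b in loci[i + 1:]:
            if a & b:
                raise FixtureError(f"overlapping defect loci: {sorted(a & b)}")
    out = model.copy()
    key = []
    jitters = []
    for d in recipe.defects:
        if d["type"] == "cis_flip":
            key.append(_apply_cis_flip(out, d["chain"], d["seq"]))
        elif d["type"] == "register_shift":
            key.append(_apply_register_shift(out, d["chain"], d["start"],
                                             d["end"], d["shift"]))
        elif d["type"] == "rotamer_scramble":
            key.append(_apply_rotamer_scramble(out, d["chain"], d["seq"],
                                               d.get("offset", 120.0)))
        elif d["type"] == "jitter":
            jitters.append(d)
        else:
            raise FixtureError(f"unknown defect type {d['type']!r}")
    rng = np.random.default_rng(recipe.seed)
    for d in jitters:
        for r in out.residues():
            for a in r.atoms:
                if not a.is_hydrogen:
                    a.position = a.position + rng.normal(scale=d["sigma"], size=3)
        key.append({"type": "jitter", "sigma": d["sigma"],
                    "expect": "nonzero per-residue displacement everywhere"})
    return out, key
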