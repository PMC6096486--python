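# flexfit

Restraint-guided molecular-dynamics flexible fitting (MDFF) for
rebuilding macromolecular models in real-space density maps — as a
headless Python library and CLI.

Models built into 3–4 Å cryo-EM or crystallographic density carry
error classes that local refinement cannot escape: spurious
cis/twisted peptide bonds, stretches of backbone modelled out of
register, and torsions forced into allowed-but-wrong conformations.
`flexfit` treats rebuilding as restrained low-temperature dynamics.
The density map ρ becomes an attractive potential over the
sigma-normalized density ρ̂ = (ρ − ⟨ρ⟩)/σ_ρ,

    E_map = −w Σᵢ ρ̂(xᵢ)        (heavy atoms, tricubic interpolation)

so atoms are pulled up the density gradient, while every manipulation
is expressed through two restraint force laws:

* flat-bottomed dihedral restraints,
  E = k(cos Δθ_cutoff − cos Δθ) outside a dead band of Δθ_cutoff
  (30° for φ/ψ/ω, 15° for χ), zero inside — periodic, with a smooth
  gradient dE/dθ = k sin Δθ everywhere;
* linear-capped springs for distance/position/tug restraints,
  F = min(k·|r − r₀|, F_max), so a far-away target pulls with constant
  force instead of a divergent one.

On top of these sit the scripted rebuilding operations: cis↔trans and
peptide-plane flips, secondary-structure and rotamer restraint bundles,
interactive-style tugging, and a register-shift engine that fits
parametric cubic splines to the backbone (N, C, Cα, Cβ) and walks every
residue along them to its neighbour's site, one register unit per ten
coordinate updates. Validation (ω classification: cis ≤ 30°,
trans ≥ 150°, twisted between; six-case Ramachandran scoring; per-residue
model-vs-model change analysis at >45°/>2 Å thresholds) runs on a fixed
cadence during dynamics, and checkpoints snapshot positions plus the
full restraint set. See `docs/methods.md` for the models, defaults and
limitations (including the synthetic Ramachandran reference tables).

## Worked example: rebuild a corrupted helix

Build a ground-truth 20-residue helix, a synthetic map from it, and a
corrupted copy carrying the two classic defect classes — residues 5–14
shifted in register by +1 and a cis peptide bond at residue 20:

```sh
flexfit make-fixture --seq AAAAAAAAAAAAAAAAAAAA --conf alpha --out truth.pdb
flexfit make-map truth.pdb --sigma 0.75 --voxel 0.5 --out map.mrc
cat > recipe.json <<'EOF'
{"seed": 1,
 "defects": [{"type": "register_shift", "chain": "A", "start": 5, "end": 14, "shift": 1},
             {"type": "cis_flip", "chain": "A", "seq": 20}]}
EOF
flexfit make-fixture --seq AAAAAAAAAAAAAAAAAAAA --conf alpha \
        --errors recipe.json --out broken.pdb
flexfit validate broken.pdb
```

The validator finds both problems at once — one nonproline cis bond,
and only 17 intact peptide bonds because the register error physically
opens the chain at the run boundaries:

```
"omega": {"cis_proline": 0, "cis_nonproline": 1, "twisted": 0,
          "trans": 16, "n_peptide_bonds": 17}
"non_trans_peptides": [{"chain": "A", "seq": 20, ... "class": "cis"}]
```

Fix the register error (splines fitted to the misplaced run; the edge
residue must travel into the vacated site, hence extrapolating ends),
flip the cis bond under the map's guidance, then settle everything
against the density:

```sh
flexfit shift-register broken.pdb --chain A --start 5 --end 14 --shift -1 \
        --ends extrapolate --seed 1 --out step1.pdb
flexfit flip-cis-trans step1.pdb --chain A --residue 20 \
        --map map.mrc --weight 20 --seed 1 --out step2.pdb
flexfit settle step2.pdb --map map.mrc --weight 20 --steps 800 --seed 1 \
        --out final.pdb
flexfit validate final.pdb
flexfit compare truth.pdb final.pdb --out delta.tsv --json summary.json
```

`validate` now reports a fully ligated, all-trans chain:

```
"omega": {"cis_proline": 0, "cis_nonproline": 0, "twisted": 0,
          "trans": 19, "n_peptide_bonds": 19}
```

and `compare` (per-residue Δφ/Δψ/Δω and heavy-atom RMSD versus the
ground truth, flagged at >45° / >2 Å) shows the rebuild: before
correction 55% of residues were displaced by more than 2 Å; after it,
10% (the two residues flanking the re-ligated gap retain some strain):

```
truth vs broken:  "moved_percent": 55.0, "combined_percent": 55.0
truth vs final:   "moved_percent": 10.0, "combined_percent": 30.0
```

Every Cα lands within 1.0 Å of the ground truth (overall heavy-atom
RMSD 0.88 Å, dominated by the re-ligated edge).

The same operations are available as a library — `build_ideal_peptide`,
`inject_errors`, `RegisterShiftPlan`/`execute_register_shift`,
`settle_model`, `peptide_bond_report`, `compare_models`,
`save_checkpoint`/`restore_checkpoint` — see the module docstrings
under `src/flexfit/`.

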