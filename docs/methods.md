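# Methods

This note records the models, numerical choices and limitations behind
`flexfit`. Everything quantitative below is computed by the test suite or
by `scripts/acceptance.py`; nothing is quoted from elsewhere.

## The problem and the approach

Models built into 3–4 Å density are dominated by errors that pure
refinement cannot escape: spurious cis and twisted peptide bonds,
backbone stretches modelled out of register, and torsions force-fitted
into allowed-but-wrong conformations. `flexfit` treats rebuilding as
restrained molecular dynamics: the density map becomes an attractive
potential, corrections are expressed as restraints with well-behaved
force laws, and geometry validation runs on a fixed cadence during the
simulation so the effect of every manipulation is measurable
immediately.

## Restraint force laws

**Flat-bottomed dihedral restraint.** For a dihedral θ with target θ₀
and Δθ = wrap(θ − θ₀):

    E = 0                                   |Δθ| ≤ Δθ_cutoff
    E = k (cos Δθ_cutoff − cos Δθ)          otherwise

The cosine form is chosen over a harmonic in Δθ because it is periodic
and its gradient, dE/dθ = k sin Δθ, vanishes smoothly at Δθ = 180°
instead of producing a gradient discontinuity when the target lies
opposite the current angle. The price is a metastable zero-gradient
point exactly at Δθ = 180°, which is negligible at working spring
constants. Defaults: k = 250 kJ/mol, Δθ_cutoff = 30° for φ/ψ/ω and 15°
for side-chain χ — backbone dihedrals routinely wander tens of degrees
from ideal values, so a restraint must be silent inside that band.

On model load only the ω (peptide-bond) dihedrals are restrained, each
to its nearer planar state (0° or 180°): interactive forces are large
enough to flip peptide bonds accidentally, and that is the one class of
geometry that should never change silently. A pre-existing cis proline
therefore keeps a 0° target rather than being forced to trans.

**Linear-capped spring** (distance, position and tug restraints):

    F = k·|r − r₀|   while k·|r − r₀| ≤ F_max,  else F_max

with the energy taken as the unique C¹ integral (quadratic below the
crossover r_c = r₀ + F_max/k, linear above). Capping the force is what
makes restraints safe to drop onto a badly wrong model: a distant
target tugs with constant force instead of a divergent one. Defaults
k = 500 kJ/mol/Å², F_max = 100 kJ/mol/Å, chosen so one restraint
dominates thermal motion at 100 K (k_BT ≈ 0.83 kJ/mol) without being
able to eject an atom through its neighbours. No published values exist
for these constants; they are package defaults and fully configurable.

**Scripted operations.** A cis↔trans flip toggles the ω target to the
planar state farther from the current angle (so it is an involution).
A peptide-plane flip adds temporary restraints on ψ of the preceding
residue and φ of the selected one, each targeted 180° away; they
auto-release when both are within the flat-bottom cutoff of their
targets, or with a logged warning after 500 coordinate updates (the
budget is a package choice). Secondary-structure bundles combine φ/ψ
restraints at canonical targets (helix −57/−47, strand −119/113) with
O(n)–N(n+4) distance restraints at 3.0 Å (helix only) and
Cα(n)–Cα(n+2) restraints at 5.43 Å (helix) or 6.8 Å (strand) —
standard textbook geometry. Rotamer targets restrain each χᵢ at a 15°
cutoff; a deliberately minimal most-common-rotamer table ships for the
18 χ-bearing residue types.

## The map as a potential

A real-space grid ρ is sigma-normalized, ρ̂ = (ρ − mean)/σ, and coupled
as E = −w·Σᵢ ρ̂(xᵢ) over enabled heavy atoms, so forces point up the
density gradient. The linear-in-density form is the simplest one that
attracts atoms into density maxima; normalization makes the weight w
(kJ/mol per normalized-density unit) transferable across maps, and the
CLI deliberately has no default for w because a sensible value depends
on the map. Hydrogens feel no map force (invisible at these
resolutions). Interpolation is tricubic Catmull–Rom — C¹, with the
gradient returned as the exact derivative of the interpolant, which
dynamics needs for stability; trilinear is available as a fallback.
Atoms outside the interpolable margin feel no map force. Masking zeroes
voxels beyond a cutoff (default 4 Å) from a selection and is
idempotent. Only orthogonal real-space grids are supported; no
structure-factor handling, sharpening or FSC computation.

The synthetic-map generator places a unit-amplitude isotropic Gaussian
(width `resolution_sigma`) on every heavy atom. With σ = 0.75 Å and
0.5 Å voxels it emulates a well-resolved map in which individual atoms
blur together along bonds — adequate for parameter-recovery tests, but
it reproduces none of the pathologies of experimental cryo-EM maps
(anisotropy, local resolution variation, noise, masking artefacts), so
passing recovery tests demonstrates correctness of the machinery, not
performance on real data.

## Register shifting

Backbone splines (natural interpolating cubics, one per atom type N, C,
Cα, Cβ, parameterized by residue ordinal) are fitted to a contiguous
run; glycines simply contribute no Cβ control point. To shift by n
register units, each residue's four backbone atoms are tugged by moving
position restraints whose targets advance along the splines, one
register unit per ten coordinate updates (20 timesteps each). Spline
lookups beyond the fitted range clamp to the run ends (linear
extrapolation is available but off by default — clamping never invents
geometry). Side chains are not restrained during the move; they follow
their backbone. Executing a plan removes every pre-existing restraint
on the selection and installs, as part of its own bundle, flat-bottom ω
restraints over the run and its two boundary bonds ("ω keepers",
targeting trans except for a measurable cis-proline): the maintenance
force field treats cis and trans symmetrically, so without them a
peptide under large transport forces can flip and become trapped. After
traversal the restraints hold at the final targets until explicitly
released, and the recommended procedure is to energy-minimize *before*
releasing: the restraints define the new register, and minimizing under
them locks the backbone in before the force field takes over. Register-shift execution defaults to a low
simulation temperature (20 K): a large coordinated move tracks its
moving targets most faithfully with little thermal noise, and the final
state is minimized anyway. Recovery of an injected one-residue register
error on a 20-mer helix lands the interior backbone well inside the
0.5 Å band (measured by the acceptance script).

## Validation

ω classes: cis |ω| ≤ 30°, trans |ω| ≥ 150°, twisted in between. The 30°
boundary follows the convention of the standard validation ecosystem;
ultrahigh-resolution surveys show real peptides twist 10–20° routinely
but almost never beyond 30°, which is what makes twisted and
cis-nonproline bonds strong error signals (genuine cis-nonproline bonds
occur at roughly 5 per 10,000 residues). Both thresholds are
configurable.

Ramachandran scores use six cases (general, Gly, cis-Pro, trans-Pro,
pre-Pro, Ile/Val) with class boundaries on a percent scale: outlier
P < 0.05, marginal 0.05 ≤ P < 2, favoured P ≥ 2. **The bundled
reference distributions are synthetic**: wrapped-Gaussian mixtures over
(φ, ψ) whose components sit on the canonical basins, converted to a
percentile score P(φ,ψ) = 100·Pr[density(X) ≤ density(φ,ψ)] on a 2°
grid with bilinear, wrap-around lookup. This reproduces the *semantics*
of contour-based validation (peaks score near 100, empty regions score
under 0.05) and behaves correctly on the canonical conformations, but
absolute outlier percentages on real structures will not match scores
computed from empirically derived tables — reproducing deposited-model
outlier rates requires swapping in such tables. Cα colouring maps log P
from maroon (outlier boundary) through yellow to green (favoured
boundary), monotone in log P.

Model comparison matches residues by (chain, seq, insertion code) and
reports wrapped Δφ/Δψ/Δω plus per-residue heavy-atom RMSD over shared
atoms, flagging >45° or >2 Å. No superposition is applied by default
because the intended comparison is between models refined against the
same map (a shared frame); a global Cα superposition is available as an
option.

## Dynamics engine

Force providers are additive and pluggable; the built-in set is the
geometry-maintenance force field, the restraint set and any map
potentials. The force field maintains covalent geometry and excluded
volume and nothing else: harmonic bonds and angles at ideal values
(taken per residue from ideal component geometry, with backbone terms
pinned to the same constants the fixture builder uses), periodic
planarity terms E = k(1 − cos 2θ) on peptide ω quadruples and aromatic
ring torsions (minima at both planar states), and a soft-sphere
repulsion ε(σ/r)¹² (ε = 4 kJ/mol, σ = 2.7 Å, truncated and shifted at
3.2 Å) over heavy-atom pairs more than three bonds apart, with the
pair force capped at 10⁴ kJ/mol/Å so that badly clashed starting
models minimize instead of exploding. Two further choices matter for
rebuilding work: consecutive residues are *ligated* (given a peptide
bond term) whenever their C–N separation is under 5 Å, so geometry
opened or compressed by an error — a register shift squeezes one
peptide and stretches another — is pulled back together during
settling, while true chain breaks stay free; and bond forces switch to
a constant 2000 kJ/mol/Å beyond 0.5 Å of stretch, so re-ligation tugs
gently instead of yanking the neighbouring residues. There are no electrostatics, no
solvent model, no attractive dispersion and no torsional preferences
beyond planarity: φ/ψ/χ equilibria are supposed to come from restraints
and the map, and validation deliberately measures rather than biases
them. A full biomolecular force field can be substituted behind the
same provider contract.

Integration is BAOAB Langevin, timestep 1 fs, friction 10 ps⁻¹,
default temperature 100 K — low-temperature settling, not equilibrium
sampling. At T = 0 the integrator is damped descent. Every 20 timesteps
(one "coordinate update") moving restraints advance and temporary
restraints are checked; validation summaries refresh every 10
coordinate updates. A step moving any atom more than 1 Å aborts with a
diagnostic. The noise stream is seeded, so identical seeds give
identical trajectories. Minimization is L-BFGS on the mobile atoms with
a maximum per-atom force stopping criterion; the energy trace over
accepted iterates is non-increasing. Fixed-shell atoms (selection
expansion: ±3 residues along the chain, then 5 Å neighbours, with a 5 Å
fixed shell — the shell thickness is a package choice) are pinned
exactly.

Checkpoints snapshot positions, velocities and a deep copy of the
restraint set; restores are bit-identical in positions and exact in
restraints, any number of checkpoints may coexist, and they serialize
to JSON so a session can be resumed from disk.

The `settle` pipeline is minimize → Langevin at T → minimize at 0 K,
with validation reports before and after. Problem sizes in the tests
and the acceptance script (20-residue fixtures, a few hundred Langevin
steps, ~0.5 Å-scale defects) are chosen so every pipeline runs in
seconds while still exercising each code path at realistic geometry;
recovery thresholds (interior backbone RMSD < 0.5 Å after register
correction, heavy-atom RMSD < 0.2 Å after MDFF settling of a 0.3 Å
jittered helix) are comfortably met at these sizes.

## Error injection and ground truth

`ErrorRecipe` injects defects with an exact answer key. The cis flip is
implemented as a torsion drive: all atoms downstream of the peptide
C–N bond rotate rigidly about that bond by −ω, setting ω to exactly 0
while changing no other internal coordinate (a strictly local Cartesian
edit cannot reach ω = 0 from trans, so internal-coordinate locality is
the right notion here). Register-shift injection runs the spline
machinery in reverse — backbone atoms move to the spline positions of
their neighbours n away, side chains ride along rigidly — producing
exactly the error geometry the corrector is designed for. Rotamer
scrambling torsion-drives χ1; jitter adds seeded Gaussian noise to
heavy atoms. Defect loci must not overlap, except jitter, which is
global.

## Known limitations

- The force field is a geometry keeper, not a physical model: no
  hydrogen bonding, electrostatics or solvation, so it cannot rank
  conformations energetically.
- Synthetic Ramachandran contours (above): class boundaries are
  honoured, absolute percentages on real data are not comparable to
  scores from empirical tables.
- Ligands and metals have no bonded parameters; single-atom het groups
  participate only in repulsion and may be position-restrained.
- Maps must be orthogonal real-space grids; no crystallographic
  symmetry.
- Hydrogens are tolerated but ignored by validation RMSDs, map forces
  and nonbonded repulsion.
- Disulfides and other inter-chain covalent links are not bonded in the
  force field.
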