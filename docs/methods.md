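# Methods

This note documents the models, numerical choices and limitations behind
`protrefine`, in the order the pipeline applies them.

## Structure model and internal coordinates

A structure is a single chain of the 20 standard amino acids. Reading
goes through Bio.PDB (HETATM records, waters and alternate locations
other than `A`/`' '` are dropped; hydrogens are kept; `OXT` and other
non-template heavy atoms are silently ignored); writing emits
fixed-column ATOM records at 3-decimal precision. An input is valid when
every residue has N/CA/C/O, residue numbers increase consecutively, and
each peptide C–N distance is below 2.5 Å (covalent ≈ 1.33 Å; the slack
tolerates distorted models). Torsions follow the IUPAC sign convention —
verified against crystal-structure backbone geometry, which is also the
source of the L-configuration Cβ improper (dihedral C–N–CA–CB =
−122.6°). Setting a torsion rotates exactly the atoms distal of the
axis in the bond graph, so bond lengths and angles are preserved to
machine precision. Proline φ and χ are never rotated: the pyrrolidine
ring makes them ill-defined as single degrees of freedom, so proline
side chains ride along rigidly.

Missing hydrogens are added by ideal-geometry rules (tetrahedral,
trigonal, methyl-staggered, hydroxyl-trans placements from the local
heavy-atom frame; N–H 1.01 Å, C–H 1.09 Å, O–H 0.96 Å, S–H 1.34 Å). The
N-terminus receives a single amide-style hydrogen rather than a charged
NH3+ cap; termini are likewise left un-ionized. Charged side chains
(Asp/Glu/Lys/Arg) carry formal charges through a reduced partial-charge
set; His is modeled neutral with the proton on NE2.

## Side-chain rebuilding

The rotamer library is a compact backbone-independent set of canonical χ
wells with literature-style probabilities, shipped as TSV
(`protrefine/data/rotamer_library.tsv`); an external library in the
same dialect can be loaded instead. Burial is measured two ways: the
conformation-independent Cβ-neighbor count (Cβ atoms of other residues
within 8 Å; a virtual Cβ is built for glycine) orders residues
core-first and assigns the exposure class (exposed ≤ 4, intermediate
5–9, buried ≥ 10 neighbors), and the conformation-dependent count
around the side-chain centroid feeds the burial filter. The filter's
intervals are the 5th–95th percentiles of centroid counts per (residue
type, exposure class) over a synthetic ideal-geometry corpus, padded by
±2 neighbors because the corpus is small and unpadded intervals would
revert most rebuilt residues. Clashes are vdW overlaps > 0.4 Å with
Probe-style contact radii (C 1.70, N 1.55, O 1.40, S 1.80, H 1.17,
polar H 1.00 Å), pairs within three bonds excluded. When every rotamer
of a residue clashes, the rotamer with the smallest summed overlap is
kept, which guarantees termination.

## Energy function

The total energy is `E_phys + w_db·E_db + w_rst·E_rst`. Only the 5×
mild/aggressive ratio of the restraint weight is fixed by the protocol;
the absolute values (`w_rst` 1.0 mild / 0.2 aggressive, `w_db` 1.0,
restraint constant k = 0.5 kcal·mol⁻¹·Å⁻² on heavy atoms) are package
defaults exposed in the configuration.

Physics terms: harmonic bonds and angles whose equilibrium values are
measured from ideally built G-X-G tripeptides (so an ideal structure is
strain-free by construction; force constants 300/340 kcal·mol⁻¹·Å⁻² for
heavy/H bonds, 50/35 kcal·mol⁻¹·rad⁻² for angles), a two-fold cosine
term holding ω planar, Lennard-Jones with element-based parameters,
Coulomb under a distance-dependent dielectric ε(r) = 4r, a
Lazaridis–Karplus-style Gaussian-exclusion implicit-solvation term, and
a surface-area term. Nonbonded interactions use a 12 Å cutoff with a
C1 switching function from 10 Å and exclusion of 1-2/1-3/1-4 pairs.

The surface-area term is a smooth occlusion proxy (per-atom exposed
area decays exponentially with a switched neighbor count) rather than a
Shrake–Rupley area: an exact sphere-point SASA is piecewise-constant in
the coordinates and therefore incompatible with the analytic gradients
the dynamics needs. The proxy keeps the term's slot and sign convention
so an exact SASA could be swapped in for scoring.

Database terms: backbone torsion propensities are a periodic Gaussian
mixture over the α, β, PPII and left-handed-α basins, side-chain
propensities a mixture over the library rotamers (width 30°), both
scored as −ln P. The residue-pair term applies a smooth
shallow-well/soft-shoulder radial profile between Cβ atoms (sequence
separation ≥ 2), scaled by the product of residue hydrophobicities, and
is evaluated through a cubic spline over 0.5 Å bins so externally
supplied tables in the same binning drop in directly
(`export_bb_grid` writes the backbone table at 10° resolution).
Backbone hydrogen bonds use a 10–12 radial well (optimum H···O 2.0 Å,
depth 2 kcal·mol⁻¹) times a squared-cosine N–H···O angular factor.

Every term has an analytic gradient (dihedral derivatives via the exact
Blondel–Karplus expressions); the test suite checks all of them against
central differences at 1e-4 relative tolerance. The restraint is the
only frame-anchored term — everything else is rigid-motion invariant.

## Minimization and dynamics

Minimization is L-BFGS on the composite energy, stopping at the
iteration cap or a projected-gradient infinity-norm below
1e-3 kcal·mol⁻¹·Å⁻¹. Relaxation segments are Langevin dynamics with a
BAOAB splitting at 300 K and friction 5 ps⁻¹. The 4 fs timestep is made
stable by hydrogen-mass repartitioning (H mass 3 amu borrowed from the
bonded heavy atom) plus SHAKE/RATTLE-style iterative projection of X–H
bond lengths. Velocities are drawn from the Maxwell–Boltzmann
distribution with the segment seed, making every trajectory
bit-reproducible. In the zero-friction, no-thermostat limit at 0.5 fs
the integrator conserves total energy to well under 1% over 1000 steps
(checked in the tests after a 10-step settling prefix, which absorbs
the initial equipartition transient).

## Triaxial loop closure

With all non-pivot torsions frozen, the three pivot CA atoms form a
triangle with fixed side lengths whose outer vertices are anchored, so
the middle CA moves on a circle parametrized by one angle σ. For each σ
the pivot-1 carbonyl carbon and the pivot-3 amide nitrogen each solve a
cone/sphere intersection (≤ 2 branches each); the inter-pivot bodies are
rigid (every ω is held), so their placement follows from three anchor
points, and one scalar condition remains — the N–CA–C angle at pivot 2.
Scanning σ on a 256-point grid for each of the four branch
combinations, bracketing sign changes with Brent's method, and
Gauss–Newton-polishing the six (φ, ψ) torsions on a backbone-only
kinematic model yields all solutions (at most 16), each verified to
reproduce the C-side stem within 1e-6 Å by full forward kinematics.
Solutions are de-duplicated (0.01° tolerance) and sorted by torsional
distance from the input. Unreachable anchors (triangle inequality
violated) return an empty list; collinear stems raise an error.
Perturb-and-close draws Gaussian noise on the non-pivot (φ, ψ), closes,
applies the solution nearest the input, and snaps the (already
machine-precision-correct) downstream residues exactly onto their
original coordinates; failed closures reject the move and return the
input.

## Protocol

Defaults are the full protocol constants: pools of 32 trajectories,
22 mild / 17 aggressive cycles, 0.6 / 0.8 ps segments at 4 fs, five
output models, four cluster representatives. Trajectory *i* uses seed
`master_seed + i`; all randomness flows from these seeds. Each cycle is
perturb → minimize (≤ 50 steps; a brief regularization before dynamics)
→ MD segment. Mild perturbations re-draw probability-weighted rotamers
for all residues whose Cβ lies within 6 Å of a random seed residue.
Aggressive perturbations pick one target per cycle among coil stretches
(≥ 3 residues; torsion noise σ = 10° plus closure) and
secondary-structure elements (rigid shift ≤ 0.5 Å, rotation ≤ 5°, with
closure of the flanking coils); targets whose flanks cannot be closed
are rejected and logged. Secondary structure is assigned from torsion
ranges, with helix runs corroborated by an i→i+4 backbone hydrogen
bond. Restraints anchor heavy atoms to the rebuilt starting model: the
rebuild is deliberate, so tethering side chains to their pre-rebuild
positions would undo it, while the rebuilt backbone equals the input
backbone. Selection energies are totals under the regime that produced
the pool. Clustering is average-linkage on pairwise CA RMSD cut at
2 Å; clusters are ordered by size (ties by lowest member index) and
represented by the member with the lowest mean RMSD to its cluster.

Side chains are rebuilt once, before the pools — not between cycles;
the mild regime's rotamer re-draws already act as per-cycle repacking
moves.

## Quality metrics

GDT-HA is the mean coverage at 0.5/1/2/4 Å over CA atoms; the maximal
coverage per threshold is estimated by iterative superposition (align
on the current inlier set, re-select inliers, repeat to a fixed point)
started from every contiguous 5-residue window plus the global
alignment. On small structures with structured errors this equals an
exhaustive search over all contiguous seed windows (verified in the
tests at 25 residues); under large diffuse noise any finite seed search
is heuristic. GDC-SC applies the 10-threshold (0.5…5.0 Å) linearly
weighted (10…1) GDC formula to one characteristic atom per residue
type (e.g. LEU CD1, ARG NH1, SER OG; glycine excluded) under the same
CA-based superposition search. Clashscore is 1000 × (≥ 0.4 Å-overlap
pairs) / atoms, with hydrogens added first. A residue is a rotamer
outlier when its χ vector is farther than 40° (per angle, circular)
from every library rotamer. Ramachandran-favored uses coarse
rectangular favored regions per class (general / GLY / PRO),
approximations of the usual kernel-density contours; terminal residues
are excluded. The MolProbity-style score is the standard closed form
`0.42574·ln(1+clash) + 0.32996·ln(1+max(0,rot−1)) +
0.24979·ln(1+max(0,(100−rama)−2)) + 0.5`, so (0, 0, 100) scores exactly
0.5 and experimental structures typically land between 1 and 2.

## Synthetic fixtures

`build_peptide` constructs ideal-geometry chains (Engh–Huber-style
bonds and angles, exact requested backbone torsions, side chains at the
top rotamer) and can plant defects: scrambled χ, forced Cβ–Cβ
overlaps, displaced or deleted residues, chain splits. `make_decoy_pool`
plants k conformational modes (large ψ changes at the central residue)
plus Gaussian coordinate noise and returns mode labels for
planted-truth tests. These fixtures exercise every code path but do not
emulate real model errors: they have no packing defects of native
cores, no register shifts, no missing atoms, and their statistical
terms were not fitted to real structures — so passing tests demonstrate
algorithmic correctness and the direction of quality changes, not
refinement power on real predictions. Protocol-scale quantities in the
tests and the acceptance script run on 8–20-residue peptides with
shortened relaxation segments (the desk preset: pools of 4, 2 cycles,
0.04 ps), a deliberate problem-size choice for a reproducible suite;
cycle counts, pool sizes and selection logic are exercised at their
full default values.

## Known limitations

- The bonded parameter set is reduced (template-derived equilibria,
  generic force constants); it preserves the functional forms of a
  CHARMM-style force field, not its exact constants.
- Implicit solvation is a Gaussian-exclusion approximation and the
  surface term a smooth proxy; neither is a self-consistent
  generalized-Born/FACTS model.
- The residue-pair and torsion-propensity terms are analytic forms, not
  potentials of mean force derived from the PDB; loader hooks accept
  real tables.
- The rotamer library is backbone-independent and coarse (2–6 rotamers
  per type).
- Proline is never repacked or used as a closure pivot.
- Single chains only; no ligands, nucleic acids, insertion codes or
  multi-model files.
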