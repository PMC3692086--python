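# protrefine

Refinement of predicted protein structures at desk scale: side-chain
rebuilding from ranked rotamers, restrained molecular-dynamics relaxation
in a *mild* and an *aggressive* regime, analytic triaxial loop closure,
and energy/cluster-based selection of five output models — together with
the model-quality metrics commonly used to judge the result (CA RMSD,
GDT-HA, GDC-SC, clashscore, rotamer outliers, Ramachandran-favored
fraction and a MolProbity-style composite score).

## Who this is for

Template-based protein models are usually less accurate in their side
chains and loops than in their core backbone. `protrefine` takes a
single-chain model in PDB format (no internal gaps) and tries to improve
its local quality while staying near the input: the kind of polishing
step run after homology modelling and before using a model for design or
interpretation. Everything is testable offline: a synthetic-structure
generator builds ideal-geometry helices, strands, coils and decoy pools,
so no external structure files are required.

## The method

1. **Side-chain rebuild.** All side chains are rebuilt from a ranked
   rotamer library, core residues first (descending Cβ-neighbor count,
   processed in quintile layers). Each residue takes its
   highest-probability rotamer that creates no new steric clash against
   the backbone and already-placed side chains; if every rotamer clashes,
   the least-clashing one is kept. A burial filter then restores the
   input conformation of any residue whose rebuilt side chain is packed
   unlike the canonical expectation for its type at the same exposure.

2. **Two relaxation regimes.** Starting from the rebuilt model, each of
   32 independent trajectories per regime runs repeated cycles of
   *perturb → minimize → short MD* (22 cycles mild, 17 aggressive; MD
   segments of 0.6 and 0.8 ps at a 4 fs timestep). Mild cycles perturb
   only clusters of side chains; aggressive cycles apply larger moves to
   secondary-structure elements and loops, with **triaxial loop
   closure** solving the three pivot residues' (φ, ψ) analytically so
   the chain never breaks. The energy is a linear combination of
   physics terms (bonded, Lennard-Jones, screened Coulomb, implicit
   solvation, surface area), database terms (backbone/side-chain torsion
   propensities, residue-pair potential, backbone hydrogen bonds), and a
   harmonic restraint to the starting model whose weight is **five times
   larger in the mild regime** than in the aggressive one.

3. **Model selection.** The lowest-energy member of the mild pool is
   returned as model 1. The aggressive pool is clustered by pairwise CA
   RMSD (average linkage, 2 Å cutoff) and the members closest to the
   four largest clusters become models 2–5.

## Worked example

```bash
python - <<'PY'
from protrefine.fixtures import FixtureSpec, build_peptide
from protrefine.pdb_model import write_pdb
spec = FixtureSpec("AVKLDEFSTAYHQNMRWICG", conformation="strand",
                   defects=[("scramble_chi", {"residue": 6,
                                              "chi": [-177.0, 55.0]})])
open("decoy.pdb", "w").write(write_pdb(build_peptide(spec)))
PY
protrefine refine decoy.pdb --preset desk --seed 11 --out refined
cat refined/report.tsv
```

prints (desk preset: pools of 4, 2 cycles per trajectory, 0.04 ps MD):

```
model	rmsd	gdt_ha	gdc_sc	clashscore	rotamer_outliers_pct	rama_favored_pct	molprobity
model_1	0.124	100.000	92.919	0.000	0.000	100.000	0.500
model_2	0.117	100.000	93.780	3.125	0.000	100.000	1.103
model_3	0.148	100.000	92.823	18.750	0.000	100.000	1.770
model_4	0.128	100.000	94.737	6.250	0.000	100.000	1.343
model_5	0.118	100.000	93.780	6.250	0.000	100.000	1.343
```

Each row scores one output model against the input decoy. The scrambled
phenylalanine that clashed with the backbone has been repacked: the
input scores clashscore 3.1 and MolProbity-style score 1.10, model 1
scores 0.0 and 0.50 — improved physical correctness while the backbone
stays within ~0.1 Å of the input (rmsd column). Models 2–5 come from
the aggressive pool and scatter more. `protrefine score model.pdb
ref.pdb` prints the same row for any pair of structures.

The default configuration (pools of 32, 22/17 cycles, 0.6/0.8 ps
segments) is the full protocol scale and takes hours of CPU;
`--preset desk` is the reduced configuration used throughout the test
suite. All constants can be overridden with a YAML file via `--config`.

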