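# qubodock

Fragment-based protein–ligand flexible docking formulated as a quadratic
unconstrained binary optimization (QUBO) problem.

Classical docking must search a compound's translations, rotations, *and*
internal torsions at once. `qubodock` instead decomposes the compound into
rigid fragments, takes many candidate 3D placements of each fragment in the
binding pocket (from an external fragment-docking engine, or synthetically),
and turns "pick one placement per fragment that scores well and fits
together" into minimizing a four-term Hamiltonian over binary variables
`x_i` (one per candidate placement):

```
H = A·H1 + B·H2 + C·H3 + D·H4        with defaults (A,B,C,D) = (1, 5, 5, 25)

H1 = Σ ΔG_i x_i              binding free energy of accepted placements
H2 = Σ clash(i,j) x_i x_j    penalty for sterically clashing pairs
H3 = Σ conn(i,j) x_i x_j     reward (−1) for pairs that can form their bond
H4 = ½ Σ_k (Σ_{i∈S_k} x_i − 1)² + ½ Σ_k Σ_{i∈S_k} x_i(1−x_i)
                             exactly one placement per fragment k
```

`clash` and `conn` are binarized from UFF pair energies against a tolerance
of 500 kcal/mol (or from pure distance criteria in a fast geometric mode).
The QUBO is solved by an exhaustive oracle (small instances) or by
multi-restart simulated annealing, valid solutions are filtered
(one placement per fragment), and each is reconstructed into a docked
compound pose whose heavy-atom RMSD against a reference can be evaluated in
the protein frame. A planted-instance generator makes the whole pipeline
testable without any external docking tool.

Intended users: computational chemists and method developers studying
combinatorial/annealer-based docking formulations. The package is a
proof-of-concept pipeline, not a production docking engine: fragment
docking itself (pose generation against a protein) is consumed, not
performed.

## Worked example

Decompose the aldose-reductase inhibitor (the PDB 2HV5 redocking compound):

```
$ qubodock fragment "C1=CC=C2C(=C1)C(=NN(C2=O)CC3=NC4=CC(=CC=C4S3)C(F)(F)F)CC(=O)O"
fragment 0: Cc1n[nH]c(=O)c2ccccc12
fragment 1: Cc1nc2ccccc2s1
fragment 2: FC(F)F
fragment 3: O=CO
4 fragments, 3 bonds
```

The four rigid fragments are the phthalazinone and benzothiazole ring
systems (each keeping its linker CH2 as a methyl), the CF3 group, and the
carboxylic acid, each capped with hydrogen at the cut bonds.

Run the full pipeline on a planted synthetic instance (4-fragment chain,
6 placements per fragment, overlapping score distributions):

```
$ python scripts/acceptance.py --seed 1 --out results/acceptance.json
subregions in the reference docking box: 343
instance: 24 variables, 216 pair terms
annealer pool: 44 solutions, 38 valid (86.4%)
best valid solution: H = -34.2457 (H1 = -19.2457, H2 = 0.0, H3 = -3.0, H4 = 0.0)
RMSD of reconstructed pose to planted ground truth: 0.000 A
```

Reading the output: the 14 Å docking box tiles into 343 subregions of 2 Å;
the annealer's valid solutions select one placement per fragment (H4 = 0);
the best one is clash-free (H2 = 0), forms all three inter-fragment bonds
(H3 = −3), and reconstructs exactly the planted ground-truth pose (RMSD
0 Å).

The same stages are available as subcommands for external pose data:
`qubodock ingest` (score filter, per-subregion caps, RMSD deduplication),
`qubodock pairterms`, `qubodock build` (QUBO export as JSON / qbsolv-style /
dense matrix), `qubodock solve`, `qubodock reconstruct`, and
`qubodock evaluate` (docking RMSD). `qubodock synth` writes a complete
planted instance directory.

## Library use

```python
import qubodock as qd

inst = qd.generate_instance(qd.GeneratorConfig(seed=1))
problem = inst.qubo()
pool = qd.postprocess_filter(
    qd.simulated_anneal(problem, qd.SolverConfig(seed=1, restarts=300, sweeps=60)),
    problem.groups,
)
pose = qd.assemble(pool.best, inst.placements, inst.fragmentation)
```

## Acceptance script

`scripts/acceptance.py --seed <int> --out <path>` runs the package's main
computation end to end — subregion enumeration for the reference docking
box, planted-instance generation, pair terms, QUBO assembly, simulated
annealing, validity filtering, pose reconstruction, and RMSD against the
planted ground truth — printing the run summary and writing the JSON result
mapping to `--out`. All randomness derives from `--seed`.

See `docs/methods.md` for the model details, parameter defaults, the
synthetic generator's scope, and known limitations.
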