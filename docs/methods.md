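# Methods

## The model

`qubodock` formulates fragment-based protein–ligand flexible docking as a
quadratic unconstrained binary optimization (QUBO) problem. A compound is
decomposed into rigid fragments (substructures without internal rotatable
bonds). Candidate 3D placements of each fragment in the binding pocket —
produced by an external fragment-docking engine or by the built-in synthetic
generator — are each mapped to one binary variable `x_i ∈ {0, 1}`. Selecting
a consistent, well-scoring set of placements, one per fragment, minimizes

```
H = A·H1 + B·H2 + C·H3 + D·H4

H1 = Σ_i ΔG_i x_i                      fitness (binding free energy scores)
H2 = Σ_{i<j} clash(i,j) x_i x_j        steric clash penalty, clash ∈ {0, 1}
H3 = Σ_{i<j} conn(i,j) x_i x_j         covalent-bond reward, conn ∈ {−1, 0}
H4 = ½ Σ_k (Σ_{i∈S_k} x_i − 1)²
   + ½ Σ_k Σ_{i∈S_k} x_i (1 − x_i)     one placement per fragment k
```

The pair sums run over unordered pairs with a single contribution each; a
double-counting convention would only rescale B and C. The second H4 term
vanishes identically on binary inputs; it is retained in the direct
evaluator (it matters to continuous-relaxation dynamics) and contributes
nothing to the QUBO coefficients.

Default weights are `(A, B, C, D) = (1, 5, 5, 25)`: B and C are of similar
scale because both act on placement pairs, and the constraint weight D is
larger so constraint violations dominate any achievable fitness gain.

Expanding H4 with `x² = x` gives the coefficient form: `−D/2` on every
linear term, `+D` on every intra-fragment pair, and `+D/2` per fragment on a
constant offset that is tracked explicitly, so reported energies equal the
Hamiltonian itself (all-zeros selection costs `D·|F|/2`). Agreement between
the coefficient evaluation and the direct term-wise sums is a standing test.

## Fragment decomposition

A bond is cut when it is single, acyclic, and both end atoms are heavy with
at least two heavy neighbours; every open valence is capped with one
hydrogen (flagged, so downstream code can remove caps when bonds are
re-formed). Cutting alone can strand a lone linker atom — a CH2 between two
ring systems yields a methane "fragment" — so single-heavy-atom components
are merged into a neighbour, preferring a carbon attachment atom over a
heteroatom, then a ring atom over an acyclic one, then the larger component,
then the lower atom index. On the benchmark aldose-reductase inhibitor
(zopolrestat, PDB 2HV5) this reproduces the four published fragments
(trifluoromethane, formic acid, 2-methylbenzothiazole,
4-methylphthalazin-1(2H)-one) exactly; the preference order is a
reconstruction validated only against that compound, since the original
decomposition tool's tie-breaking is not public.

## Placements

The docking box (default: 14 Å cube, the published redocking setup) is tiled
into cubic cells (default 2 Å, giving 343 subregions), anchored at
`center − edge/2` with half-open intervals so every point maps to exactly
one cell — the anchoring convention is ours. Ingestion keeps only poses with
`score < 0` kcal/mol, assigns each pose to the cell containing its
heavy-atom centroid, and caps each (fragment, cell) bucket at the 20
best-scoring poses. Cross-cell deduplication is best-score-first greedy: a
pose survives iff its in-place heavy-atom RMSD to every better-scoring
survivor of the same fragment is ≥ 1 Å. Greedy-by-score is our choice of
algorithm for the stated goal (keep the best representative of each similar
group); it guarantees the global best pose of every fragment survives and is
idempotent.

## Pair energies and binarization

For placements `p_i, p_j` of different fragments, `E_NB` is the UFF
single-point energy of the two capped fragments as one system minus the
energy of each fragment alone at the same coordinates; `E_B` (bonded
fragments only) removes the two cap hydrogens at the attachment, adds the
bond, and subtracts the same isolated-fragment references. Both are pure
interaction/distortion energies: a distant pair gives exactly 0 (RDKit's UFF
non-bonded cutoff, 10 Å) and the bond's stretch/angle/dihedral distortion
appears in `E_B`. The zero-point (isolated capped fragments at identical
coordinates) is our choice — the alternative readings of the merged-molecule
energy differ only by constant internal terms, which the subtraction
removes. Electrostatics follow the RDKit UFF implementation default (none).

Binarization applies two rules in order against the tolerance
`thE = 500` kcal/mol (deliberately high, to tolerate the discretization of
placement space): `conn = −1` iff bonded and `E_B ≤ thE`; then `clash = 1`
iff `conn = 0` and `E_NB > thE`. Exclusivity `clash·conn = 0` holds by
construction.

Two shortcuts exist. A prefilter returns `(clash, conn) = (0, 0)` without
any force-field call when the minimum heavy-atom distance exceeds 8 Å (at
that range `E_NB` is below any clash threshold and no bond is geometrically
possible); its agreement with the full energy path is tested, not assumed.
A geometric mode replaces energies entirely: `conn = −1` iff the attachment
atoms lie within 1.2–2.0 Å, `clash = 1` iff any heavy atoms of a
non-connected pair approach below 2.0 Å. The thresholds are configurable;
the defaults bracket a C–C bond (1.54 Å) and van-der-Waals overlap.

## Solvers

The exhaustive oracle enumerates all `2^n` vectors (vectorized, refused
above 25 variables) and materializes the `top_k` best as solution objects;
the first is the exact global optimum.

The production solver is multi-restart simulated annealing: single-bit-flip
Metropolis with a geometric temperature schedule from `T0` (the maximum
single-flip |ΔH| on a random state, floor 1.0) down to `10⁻³·T0`, followed
by a zero-temperature quench (greedy descent to a local minimum), recording
every restart's final state. Each restart consumes its own random stream
seeded by `(seed, restart index)`, so runs are reproducible and enlarging
the restart budget never worsens the best energy found. The pool is
deduplicated by exact bit-vector equality and sorted by energy with
lexicographic tie-break. This replaces a proprietary quantum-inspired
annealer whose only relied-upon property is emitting many local solutions;
an exported instance file (JSON, qbsolv-style, or dense matrix) lets an
external annealer stand in.

The postprocess filter keeps solutions with exactly one selected placement
per fragment (`H4 = 0`) and records the retained fraction.

## Reconstruction and RMSD

Assembly concatenates the selected placements' coordinates, removes the two
cap hydrogens at every inter-fragment bond and adds the bond; atoms are not
moved, so bond distortion is visible in the raw pose. Docking RMSD is
heavy-atom, computed in the shared protein frame without superposition (the
standard redocking convention), and by default minimized over graph
automorphisms so topological symmetry (CF3, phenyl flips) does not inflate
it. Optional relaxation minimizes the pose with UFF, with protein atoms (if
provided) as fixed points — a generic substitute for the commercial
minimization used in the reference workflow; its numbers are not comparable.

## Synthetic generator

The generator emulates the statistical structure of fragment-docking output
on a compound whose ground truth is known by construction. The compound is a
chain of K cyclopropyl rings (rigid units joined by cuttable single bonds; K
= 4 by default, matching the benchmark compound's fragment count). One
3D embedding of the whole chain provides the planted placements — feasible
by construction: valid, clash-free, consecutive attachments at true bond
length. Each fragment gets m−1 decoys (m = 5 by default): planted
coordinates under a uniform random rotation and a translation of scale 3 Å
(beyond the 2 Å bond window, so decoys rarely connect by accident). Scores
are Gaussian, clipped negative: planted −6 ± 0.5 kcal/mol, decoys
−2.5 ± 1.5, mirroring the published score bands (best around −4 to −6,
worst near 0). `clash_density` (default 0.3) drops that fraction of decoys
onto another fragment's centroid, creating guaranteed steric conflicts. A
`dominated_decoys` mode makes every decoy strictly worse-scoring than every
planted placement and verifiably unconnectable, which makes the planted
vector the provable optimum — the regime used for exact-recovery tests.
Generation retries (up to 20 times) until the planted vector evaluates to
`H2 = 0, H3 = −(K−1), H4 = 0`, and fails loudly otherwise.

What a green synthetic test does *not* establish: the generator has no
protein, so ΔG scores are draws rather than physics; decoys are rigid
transforms of one conformer, not independent docking poses; the compound is
a homopolymer chain, so fragment identity plays no role. Green tests
establish the combinatorial and geometric machinery — Hamiltonian
correctness, solver quality, filter soundness, reconstruction fidelity, and
the funnel relation between H and pose error — not docking accuracy against
experiment, which requires external fragment docking and ligand preparation.

## Numerical choices and degenerate inputs

- Cap hydrogens are placed along the former bond direction at 1.09 Å.
- A compound with no cuttable bond is a single fragment; an empty placement
  set yields an `n = 0` QUBO whose offset still counts its fragments.
- Pairs of placements of the same fragment never enter H2/H3 (multiplicity
  is H4's job).
- Energy comparisons in tests use exact rule boundaries (`E_B ≤ thE`,
  `E_NB > thE`); the QUBO/direct equivalence is asserted at 1e−9 relative
  tolerance.
- The annealer clips Metropolis exponents at 700 to avoid overflow; ties
  between equal-energy solutions are broken lexicographically on the bit
  vector.

## Known limitations

- The published redocking headline (RMSD 1.26 Å on ALDR/2HV5, 0.27 Å after
  minimization) is not reproducible from this package alone: it requires
  the external fragment-docking engine, commercial ligand preparation, and
  the proprietary annealer. The pipeline (ingest → pair terms → QUBO →
  solve → reconstruct → RMSD) is complete, so supplying those inputs
  reproduces the workflow.
- UFF pair energies are evaluated pair-at-a-time per placement pair;
  no protein-aware terms beyond the ingested ΔG scores.
- Stereochemistry of double bonds across fragments is not tracked
  (cuts never break double or ring bonds, but E/Z annotation is not
  propagated to fragments).
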