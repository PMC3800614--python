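# Methods

## Model

**Lattice.** Residues occupy points of the face-centred-cubic lattice.
Every site has 12 neighbours, reached by the basis vectors
(1,1,0), (−1,−1,0), (1,0,1), (1,−1,0), (−1,1,0), (−1,0,−1) and the remaining
six ±-permutations with one zero component; the full ordered tuple is frozen
in `fccfold.lattice.BASIS_VECTORS` and every deterministic scan in the
package iterates it in that order. All lattice arithmetic is exact integer
arithmetic. A conformation is a self-avoiding walk (SAW): consecutive
residues occupy neighbouring points, no point is used twice. Besides
absolute coordinates (anchored with residue 0 at the origin) each
conformation carries its *relative encoding* — the sequence of 1-based
basis-vector indices along the chain — which is the identity used for
duplicate detection and structural-diversity measures.

**Energy.** A *contact* is a residue pair (i, j), j > i+1, on adjacent
lattice points. Two energy functions are summed over contacts:

- `energy_bm`: the empirical 20×20 residue contact potential embedded in
  `fccfold.residues.BM_MATRIX` (symmetric; e.g. Cys–Cys −3.477, Phe–Phe
  −2.467, Lys–Lys +1.339).
- `energy_hp`: −1 per contact whose two residues are both hydrophobic under
  the binary classification H = {G,A,P,V,L,I,M,F,Y,W},
  P = {S,T,C,N,Q,K,H,R,D,E}.

Both are computed by probing the occupancy map of the 12 neighbours of each
residue (O(n) in the number of residues), and are verified in the test suite
against O(n²) all-pairs oracles.

**Hydrophobic core centre (HCC).** The arithmetic mean of the coordinates of
all hydrophobic residues. Distance comparisons against the HCC are done in
exact integer arithmetic on |n_H·p − Σ|² (scaling the mean by the count), so
guidance decisions never depend on floating-point rounding.

## Move operators (`fccfold.moves`)

- **Diagonal move** — relocate interior residue i to a free lattice point
  adjacent to both chain neighbours i−1 and i+1. Candidates are scanned in
  frozen basis order; an optional `accept` predicate filters targets (this
  is the hook the macro-mutation uses).
- **Pull move** — relocate residue i to a free target adjacent to its bond
  partner on the fixed side, then drag the loose side through the vacated
  positions until the chain reconnects. The final position multiset is the
  old one minus one vacated point plus the free target, so the result is
  always a valid SAW; the operator is reversible (exhaustively verified for
  short chains in the tests).
- **Tilt move** — translate a maximal collinear run of residues to a
  parallel lattice line (shift by one of the two basis vectors orthogonal to
  the run direction) and reattach the flanks by pulling. A run covering the
  whole chain degenerates to a rigid translation.
- **Rotation** — rotate the tail beyond a pivot by one of 9 axis rotations
  (90/180/270° about x, y, z; index 0 is the identity), rejected on clash.
- **Single-point crossover** — exchange encoding tails of two parents at a
  split point; children are rejected if the recombined walk self-intersects.
- **Macro-mutation** — the composite, core-directed operator: one Bernoulli
  draw (default p = 0.2 chooses the polar class, otherwise hydrophobic)
  selects which residue class to sweep; interior residues of that class are
  traversed N→C and given their first feasible diagonal move — for
  hydrophobic residues only moves that do not increase the exact squared
  distance to the (recomputed-after-every-acceptance) HCC are allowed. The
  sweep runs `repeat` passes (default 2; the pass count is exposed because
  one pass often leaves newly enabled moves on the table while many passes
  converge to a fixed point anyway). In `guidance="bm"` mode (the BD
  variant) the HCC criterion is replaced by "not worse in search energy".

## Genetic algorithm (`fccfold.ga`)

Populations are duplicate-free ordered sets keyed by relative encoding.
Initialisation grows uniform random SAWs (restart on dead end), falling back
to a laddered family of deterministic extended walks if random growth cannot
produce further distinct members.

Each generation draws **one** operator (uniformly unless `weights` is set)
and applies it *exhaustively*:

- mutation operators scan all application sites of each member in frozen
  order; the first strictly better (lower search-energy) result replaces the
  member, otherwise the parent survives;
- crossover repeatedly draws parent pairs, enumerates all split points, and
  inserts the two best of {parents} ∪ {feasible children} (stable sort —
  ties break toward parents).

Elitism re-inserts the incumbent best if a generation would otherwise lose
it. After `stagnation_window` generations (default 20) without improvement
of the best-so-far energy, every member is diversified by a **pull-move
random walk**: up to `50·n` random feasible pull moves, tracking visited
states whose relative energy change |ΔE/E₀| lies in `energy_band` (default
5–10%) and whose encoding diversity versus the start lies in
`diversity_band` (default 10–75%); the qualifying state of maximal diversity
replaces the member (the member is kept if none qualifies). This keeps the
population near the current energy level while decorrelating structures.

Variants: `BH` (BM search energy, HCC-guided macro-mutation — the headline
algorithm), `BD` (BM energy guiding its own macro-mutation), `BM` (no
macro-mutation), `HP` (HP search energy; results still reported in BM
energy). Termination on `max_generations` and/or `time_limit`.

**Determinism.** A run is driven by one `random.Random(seed)`; wall-clock
only enters through the optional time limit and the per-generation `elapsed`
log, which is excluded from trace equality — identical `(sequence, config)`
give bit-identical `RunTrace` records.

**Defaults.** `population_size=100` matches the published setting;
desk-scale examples and tests use 8–16. `stagnation_window=20` and the two
bands mirror the published stagnation-recovery recipe.

## Evaluation (`fccfold.metrics`)

- **dRMSD** — superposition-free distance-matrix RMSD over all residue
  pairs. Lattice coordinates are scaled by 3.8/√2 Å per coordinate unit so
  that one basis step (length √2) equals the 3.8 Å mean Cα–Cα distance;
  native Cα traces are read from PDB files via Biopython.
- **Relative improvement** — RI = (E_t − E_r)/E_r × 100 (%); for RMSD
  comparisons the magnitude is reported.
- **Mann–Whitney U** — scipy's tie-corrected asymptotic two-sided test, for
  comparing final-energy samples of two search variants.
- **Progress curves** — mean best-so-far energy per generation interval
  across runs, carrying a short run's last value forward.

## Benchmarks and oracles (`fccfold.benchmarks`)

The 12 benchmark proteins (54–160 residues) ship verbatim with their
published comparison numbers (reference-search and ablation tables); a
SHA-256 digest over sequences and energy matrix is asserted at import.
Printed hydrophobic counts are stored alongside recomputed ones; where they
disagree the recomputed values are authoritative.

Synthetic sequences (`random_sequence`) draw uniformly either from all 20
residues or from the designated binary pair F (hydrophobic) / S (polar) —
emulating random HP-model instances with definite matrix entries.

Exact oracles anchor the search tests: `enumerate_saws` lists every SAW of a
short chain (first step fixed to v1 to quotient the trivial symmetry;
guarded to n ≤ 10), and `global_minimum` finds the exact optimum with an
incremental depth-first energy accumulation. Problem sizes in the test suite
(n = 8 for GA-vs-oracle runs, n ≤ 60 for energy fuzzing) are the package's
own choice: large enough to exercise every operator and small enough for
deterministic minute-scale CI.

## Limitations

- The lattice model is Cα-only; side chains, bond geometry and solvent are
  outside scope.
- Pull-move reversibility is proven exhaustively only for short chains and
  sampled beyond; the structural argument (position multiset changes by one
  point) covers all lengths.
- The published multi-hour, 50-run benchmark protocol is replaced by the
  desk-scale property battery in `tests/test_acceptance.py`; the
  variant-ordering comparison at that scale is reported as a soft check
  only, since seconds-scale budgets favour the cheapest variant.
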