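# fccfold

Ab initio, on-lattice protein structure prediction with a genetic algorithm
on the face-centred-cubic (FCC) lattice.

A protein of `n` residues is modelled as a self-avoiding walk (SAW) over the
FCC lattice (12 neighbours per site, basis steps of Euclidean length √2).
Conformations are scored with the empirical 20×20 residue contact potential
(the "BM" model), summed over all non-consecutive lattice contacts; the
binary hydrophobic/polar (HP) model (−1 per non-consecutive H–H contact) is
used both as an alternative search energy and — through the
*hydrophobic-core-directed macro-mutation* — as a structural prior that
guides the contact-potential search. The search itself is an elitist genetic
algorithm with exhaustive operator application, duplicate-free populations,
and a pull-move random walk for stagnation recovery.

## Quick start (Python)

```python
from fccfold import GAConfig, run

cfg = GAConfig(
    population_size=16,
    variant="BH",           # BM search energy + HP-core-guided macro-mutation
    max_generations=60,
    stagnation_window=10,
    seed=42,
)
result = run("MKKYTCTVCG", cfg)
print(result.summary())
```

prints (deterministically, for this seed):

```
FCC lattice GA result
  variant           : BH
  sequence length   : 10
  generations       : 60
  E_BM              : -21.42
  E_HP              : -5
  contacts H-H/H-P/P-P/total : 5/7/2/14
```

`result.best` is a `Conformation` (sequence, integer lattice coordinates,
relative basis-vector encoding); `result.trace` holds a per-generation record
of best-so-far/population energies suitable for progress plots
(`fccfold.metrics.progress_summary`).

## Quick start (CLI)

```sh
fccfold run --sequence FSFFSFSF --variant BH --pop 8 --generations 20 \
        --seed 3 --out out/
# or fold one of the 12 bundled benchmark proteins:
fccfold run --benchmark 4RXN --variant BH --time-limit 60 --seed 1 --out out/
```

writes `best.json` (the final conformation), `summary.json` and `trace.tsv`
into the output directory.

## Search variants

| Variant | Search energy | Macro-mutation guidance |
|---------|---------------|-------------------------|
| `BH`    | contact potential (BM) | hydrophobic core centre (HP prior) |
| `BD`    | contact potential (BM) | the BM energy itself |
| `BM`    | contact potential (BM) | none (baseline) |
| `HP`    | HP model      | hydrophobic core centre |

`BH` is the headline mixed-model algorithm: it searches the detailed
contact-potential landscape while the macro-mutation squeezes hydrophobic
residues toward their arithmetic mean position (the hydrophobic core
centre), importing the HP model's compact-core bias.

## Package layout

- `fccfold.lattice` — FCC basis vectors, adjacency, relative encoding.
- `fccfold.residues` — HP classification and the embedded 20×20 contact
  matrix.
- `fccfold.conformation` — the `Conformation` value type, contact
  enumeration, `energy_hp` / `energy_bm`, hydrophobic core centre.
- `fccfold.moves` — diagonal, pull, tilt, rotation, single-point crossover
  and the macro-mutation operator.
- `fccfold.ga` — populations, exhaustive generation step, stagnation
  recovery, `run()` / `GAResult`.
- `fccfold.metrics` — distance-matrix RMSD, lattice→Å scaling, relative
  improvement, Mann–Whitney U, progress curves.
- `fccfold.benchmarks` — the 12 benchmark proteins with published
  comparison numbers, synthetic sequence generation, and exact brute-force
  oracles (SAW enumeration, global energy minimum) for short chains.

See `docs/methods.md` for the model and algorithm details and the rationale
behind the default parameters.

## Reproducing results

- `python scripts/acceptance.py --seed 1 --out results/acceptance.json`
  recomputes the acceptance target (the BM energy of a constructed
  single-Phe–Phe-contact conformation, −2.467).
- `pytest -q tests/` runs the full suite, including the acceptance battery
  (`tests/test_acceptance.py`): desk checks of the published
  relative-improvement tables, brute-force energy oracles on fuzzed walks,
  move-operator invariants, pull-move reversibility, and 20 seeded GA runs
  that must recover an exhaustively enumerated global minimum. Expect a few
  minutes of runtime; everything is seeded and deterministic.
- Identical `(sequence, GAConfig)` — including the seed — reproduce
  bit-identical run traces.
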