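"""Genetic-algorithm engine: exhaustive generation, duplicate-free
populations, stagnation detection and random-walk recovery.

The search follows an elitist scheme with very little blind randomness: one
operator is drawn per generation and applied *exhaustively* — a mutation
operator scans all application sites of a member in frozen order and the
first strictly-better result replaces it (otherwise the parent survives);
crossover enumerates all split points of a parent pair and keeps the two best
of parents plus children.  Duplicates (by relative encoding) are never
admitted to a population.  When the best energy stagnates, a pull-move random
walk perturbs every member: it seeks states whose energy stays within a
narrow band of the start (default 5-10%) while the structure changes as much
as possible (10-75% of encoding positions).

Four variants expose the energy-model ablation:

``BH``
    contact-potential (BM) search energy, hydrophobic-core-guided
    macro-mutation — the headline mixed-model algorithm.
``BD``
    BM search energy, macro-mutation guided by the BM energy itself.
``BM``
    BM search energy, no macro-mutation (baseline).
``HP``
    HP search energy (final structures are still reported in BM energy),
    core-guided macro-mutation.
"""

from __future__ import annotations

import random
import time
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional

from . import moves
from .conformation import (
    Conformation,
    contact_class_counts,
    energy_bm,
    energy_hp,
)
from .lattice import BASIS_VECTORS
from .moves import MacroMutationParams

MUTATION_OPERATORS = ("rotation", "diagonal", "pull", "tilt", "macro_mutation")
ALL_OPERATORS = ("crossover",) + MUTATION_OPERATORS
VARIANTS = ("BH", "BD", "BM", "HP")


@dataclass(frozen=True)
class GAConfig:
    """All knobs of a search run."""

    population_size: int = 100
    variant: str = "BH"
    operators: Optional[tuple[str, ...]] = None  # default roster per variant
    weights: Optional[tuple[float, ...]] = None  # uniform if None
    stagnation_window: int = 20
    energy_band: tuple[float, float] = (0.05, 0.10)
    diversity_band: tuple[float, float] = (0.10, 0.75)
    max_generations: Optional[int] = None
    time_limit: Optional[float] = None  # seconds
    seed: int = 0
    macro_params: MacroMutationParams = field(default_factory=MacroMutationParams)
    init_max_tries: int = 100
    random_walk_budget_factor: int = 50  # pull budget = factor * n

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population size must be >= 2")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        for band in (self.energy_band, self.diversity_band):
            lo, hi = band
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError(f"band {band} must satisfy 0 <= lo < hi <= 1")
        if self.max_generations is None and self.time_limit is None:
            raise ValueError("set max_generations and/or time_limit")
        roster = self.roster()
        unknown = set(roster) - set(ALL_OPERATORS)
        if unknown:
            raise ValueError(f"unknown operators {sorted(unknown)}")
        if self.weights is not None and len(self.weights) != len(roster):
            raise ValueError("weights length must match operator roster")

    def roster(self) -> tuple[str, ...]:
        if self.operators is not None:
            return self.operators
        if self.variant == "BM":  # baseline: no macro-mutation
            return tuple(op for op in ALL_OPERATORS if op != "macro_mutation")
        return ALL_OPERATORS

    def search_energy(self) -> Callable[[Conformation], float]:
        return energy_hp if self.variant == "HP" else energy_bm

    def macro_guidance(self) -> str:
        return "bm" if self.variant == "BD" else "hp"


class Population:
    """A duplicate-free, ordered set of conformations sharing one sequence."""

    def __init__(self, members: Iterable[Conformation] = ()):
        self.members: list[Conformation] = []
        self._encodings: set[tuple[int, ...]] = set()
        for m in members:
            self.add(m)

    def add(self, conf: Conformation) -> bool:
        """Insert unless a member with the same relative encoding exists."""
        if conf.encoding in self._encodings:
            return False
        self.members.append(conf)
        self._encodings.add(conf.encoding)
        return True

    def remove_worst(self, energy_fn) -> None:
        worst = max(range(len(self.members)),
                    key=lambda k: energy_fn(self.members[k]))
        gone = self.members.pop(worst)
        self._encodings.remove(gone.encoding)

    def best(self, energy_fn) -> tuple[Conformation, float]:
        energies = [energy_fn(m) for m in self.members]
        k = min(range(len(energies)), key=energies.__getitem__)
        return self.members[k], energies[k]

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


@dataclass
class TraceRecord:
    generation: int
    operator: str
    best_energy: float        # best-so-far (monotone non-increasing)
    population_best: float
    mean_energy: float
    population_size: int
    stagnation_counter: int
    random_walk: bool


@dataclass
class RunTrace:
    """Per-generation log; deterministic fields only take part in equality."""

    records: list[TraceRecord] = field(default_factory=list)
    elapsed: list[float] = field(default_factory=list, compare=False)

    def best_series(self) -> list[float]:
        return [r.best_energy for r in self.records]


# ---------------------------------------------------------------------------
# Initialisation
# ---------------------------------------------------------------------------

def _random_saw(sequence: str, rng: random.Random) -> Optional[Conformation]:
    """Grow a self-avoiding walk by uniformly random feasible basis steps."""
    n = len(sequence)
    coords = [(0, 0, 0)]
    occupied = {(0, 0, 0)}
    for _ in range(n - 1):
        x, y, z = coords[-1]
        free = [
            (x + dx, y + dy, z + dz)
            for dx, dy, dz in BASIS_VECTORS
            if (x + dx, y + dy, z + dz) not in occupied
        ]
        if not free:
            return None  # dead end; caller restarts
        p = free[rng.randrange(len(free))]
        coords.append(p)
        occupied.add(p)
    return Conformation.from_coords(sequence, coords)


def fallback_conformation(sequence: str, k: int = 0) -> Conformation:
    """Deterministic extended walk: ``k + 1`` straight v1 steps, then a
    v4/v1 zig-zag.  Distinct ``k`` give distinct encodings, all valid."""
    n = len(sequence)
    enc: list[int] = []
    for step in range(n - 1):
        if step <= k:
            enc.append(1)
        else:
            enc.append(4 if (step - k) % 2 == 1 else 1)
    return Conformation.from_encoding(sequence, enc)


def initialise(
    sequence: str,
    population_size: int,
    max_tries: int,
    rng: random.Random,
) -> Population:
    """Build a duplicate-free population of random self-avoiding walks.

    Each member gets up to ``max_tries`` random-growth attempts (an attempt
    that dead-ends or duplicates an existing member is discarded); exhausted
    members fall back to the deterministic extended walks, laddered so the
    population stays duplicate-free.
    """
    pop = Population()
    fallback_k = 0
    while len(pop) < population_size:
        added = False
        for _ in range(max_tries):
            conf = _random_saw(sequence, rng)
            if conf is not None and pop.add(conf):
                added = True
                break
        if not added:
            while not pop.add(fallback_conformation(sequence, fallback_k)):
                fallback_k += 1
            fallback_k += 1
    return pop


# ---------------------------------------------------------------------------
# Exhaustive operator application
# ---------------------------------------------------------------------------

def _mutation_results(
    conf: Conformation,
    operator: str,
    config: GAConfig,
    rng: random.Random,
):
    """Yield candidate conformations of one operator in frozen scan order."""
    n = len(conf)
    if operator == "rotation":
        for i in range(1, n - 1):
            for op in range(1, len(moves.ROTATIONS)):
                res = moves.rotation_move(conf, i, op)
                if res.ok:
                    yield res.conformation
    elif operator == "diagonal":
        for i in range(1, n - 1):
            for q in moves.diagonal_candidates(conf, i):
                coords = list(conf.coords)
                coords[i] = q
                cand = moves._try_build(conf.sequence, coords)
                if cand is not None:
                    yield cand
    elif operator == "pull":
        for i, t, d in moves.enumerate_pull_moves(conf):
            res = moves.pull_move(conf, i, t, d)
            if res.ok:
                yield res.conformation
    elif operator == "tilt":
        i = 0
        while i <= n - 2:
            a, b = moves.collinear_run(conf, i)
            res = moves.tilt_move(conf, a)
            if res.ok:
                yield res.conformation
            i = b
    elif operator == "macro_mutation":
        res = moves.macro_mutation(
            conf,
            config.macro_params,
            rng,
            guidance=config.macro_guidance(),
            energy_fn=config.search_energy(),
        )
        if res.ok:
            yield res.conformation
    else:
        raise ValueError(f"unknown mutation operator {operator!r}")


def exhaustive_mutation_step(
    conf: Conformation,
    operator: str,
    config: GAConfig,
    rng: random.Random,
    energy_fn: Optional[Callable[[Conformation], float]] = None,
) -> Conformation:
    """Scan all application sites of ``operator`` in frozen order and return
    the first result strictly better (lower search energy) than the parent;
    the parent survives if no site improves."""
    energy_fn = energy_fn or config.search_energy()
    parent_e = energy_fn(conf)
    for cand in _mutation_results(conf, operator, config, rng):
        if energy_fn(cand) < parent_e:
            return cand
    return conf


def exhaustive_crossover_step(
    a: Conformation,
    b: Conformation,
    energy_fn: Callable[[Conformation], float],
) -> tuple[Conformation, Conformation]:
    """Generate children at every split point and return the two lowest-energy
    members of {parents} ∪ {feasible children}; ties break toward earlier
    generation order (parents first, then children by split point)."""
    pool: list[Conformation] = [a, b]
    n = len(a)
    for k in range(1, n):
        r1, r2 = moves.crossover_single_point(a, b, k)
        for r in (r1, r2):
            if r.ok:
                pool.append(r.conformation)
    ranked = sorted(pool, key=energy_fn)  # stable: earlier order wins ties
    return ranked[0], ranked[1]


# ---------------------------------------------------------------------------
# Generation and stagnation recovery
# ---------------------------------------------------------------------------

def generation(
    pop: Population,
    config: GAConfig,
    rng: random.Random,
    operator: Optional[str] = None,
    deadline: Optional[float] = None,
) -> tuple[Population, str]:
    """Produce the next population using one operator for the whole
    generation (drawn uniformly from the roster unless given).

    Mutation generations map every member through
    :func:`exhaustive_mutation_step`; crossover generations repeatedly draw
    random parent pairs and insert both outputs.  Duplicate results are
    skipped at insertion (the parent is retained instead where possible), and
    the incumbent best member is re-inserted if the new population would
    otherwise be worse (elitism).
    """
    energy_fn = config.search_energy()
    roster = config.roster()
    if operator is None:
        weights = config.weights
        operator = rng.choices(roster, weights=weights, k=1)[0]
    new = Population()
    if operator == "crossover":
        if len(pop) >= 2:
            attempts = 0
            limit = 5 * config.population_size
            while len(new) < config.population_size and attempts < limit:
                attempts += 1
                i, j = rng.randrange(len(pop)), rng.randrange(len(pop))
                c1, c2 = exhaustive_crossover_step(
                    pop.members[i], pop.members[j], energy_fn
                )
                new.add(c1)
                new.add(c2)
                if deadline is not None and time.monotonic() > deadline:
                    break
        if len(new) == 0:
            for m in pop:
                new.add(m)
    else:
        for m in pop:
            if deadline is not None and time.monotonic() > deadline:
                new.add(m)
                continue
            child = exhaustive_mutation_step(m, operator, config, rng, energy_fn)
            if not new.add(child):
                new.add(m)
    # elitism: never let the population best regress
    cur_best, cur_e = pop.best(energy_fn)
    _, new_e = new.best(energy_fn)
    if new_e > cur_e and new.add(cur_best) and len(new) > config.population_size:
        new.remove_worst(energy_fn)
    return new, operator


def structural_diversity(enc_a: tuple[int, ...], enc_b: tuple[int, ...]) -> float:
    """Fraction of relative-encoding positions at which two walks differ."""
    if len(enc_a) != len(enc_b):
        raise ValueError("encodings must have equal length")
    if not enc_a:
        return 0.0
    return sum(x != y for x, y in zip(enc_a, enc_b)) / len(enc_a)


def _random_pull(
    conf: Conformation, rng: random.Random, tries: int = 64
) -> Optional[Conformation]:
    """Apply one random feasible pull move, or None if none exists.

    Candidates ``(residue, direction, target)`` are rejection-sampled, which
    is cheap and near-uniform over the legal move set; if sampling fails the
    full enumeration decides whether any legal pull remains.
    """
    n = len(conf)
    coords = conf.coords
    for _ in range(tries):
        i = rng.randrange(n)
        d = -1 if rng.random() < 0.5 else 1
        if d == -1:
            if i < n - 1:
                anchor = coords[i + 1]
            else:
                anchor = coords[i] if rng.random() < 0.5 else coords[i - 1]
        else:
            if i > 0:
                anchor = coords[i - 1]
            else:
                anchor = coords[i] if rng.random() < 0.5 else coords[i + 1]
        dx, dy, dz = BASIS_VECTORS[rng.randrange(12)]
        t = (anchor[0] + dx, anchor[1] + dy, anchor[2] + dz)
        res = moves.pull_move(conf, i, t, d)
        if res.ok:
            return res.conformation
    for i, t, d in moves.enumerate_pull_moves(conf):
        res = moves.pull_move(conf, i, t, d)
        if res.ok:
            return res.conformation
    return None


def random_walk(
    conf: Conformation,
    config: GAConfig,
    rng: random.Random,
    deadline: Optional[float] = None,
) -> Conformation:
    """Perturb a conformation with random pull moves to escape stagnation.

    Walks up to ``random_walk_budget_factor * n`` random feasible pull moves,
    tracking every visited state whose relative energy change ``|ΔE/E0|``
    lies inside the energy band and whose structural diversity lies inside
    the diversity band.  Returns the qualifying state of maximal diversity
    (energy kept close, structure changed as much as possible), or the input
    if none qualifies.
    """
    energy_fn = config.search_energy()
    e0 = energy_fn(conf)
    if e0 == 0:
        return conf
    lo_e, hi_e = config.energy_band
    lo_d, hi_d = config.diversity_band
    budget = config.random_walk_budget_factor * len(conf)
    start_enc = conf.encoding
    current = conf
    best_q: Optional[Conformation] = None
    best_d = -1.0
    for _ in range(budget):
        if deadline is not None and time.monotonic() > deadline:
            break
        nxt = _random_pull(current, rng)
        if nxt is None:
            break
        current = nxt
        rel = abs((energy_fn(current) - e0) / e0)
        div = structural_diversity(current.encoding, start_enc)
        if lo_e <= rel <= hi_e and lo_d <= div <= hi_d and div > best_d:
            best_q, best_d = current, div
    return best_q if best_q is not None else conf


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

@dataclass
class GAResult:
    """Best conformation found plus the full run trace."""

    best: Conformation
    best_energy: float  # in the search model of the run's variant
    trace: RunTrace
    config: GAConfig

    def summary(self) -> str:
        hh, hp, pp, total = contact_class_counts(self.best)
        gens = len(self.trace.records)
        lines = [
            "FCC lattice GA result",
            f"  variant           : {self.config.variant}",
            f"  sequence length   : {len(self.best)}",
            f"  generations       : {gens}",
            f"  E_BM              : {energy_bm(self.best):.2f}",
            f"  E_HP              : {energy_hp(self.best):.0f}",
            f"  contacts H-H/H-P/P-P/total : {hh}/{hp}/{pp}/{total}",
        ]
        return "\n".join(lines)


def run(sequence: str, config: GAConfig) -> GAResult:
    """Search for a minimum-energy self-avoiding walk of ``sequence``.

    Loops :func:`generation` with a stagnation counter; after
    ``stagnation_window`` generations without improvement of the best-so-far
    energy, every member is diversified by :func:`random_walk` (re-de-
    duplicated).  Terminates on ``max_generations`` and/or ``time_limit``.
    Identical ``(sequence, config)`` (including seed) yields a bit-identical
    trace.
    """
    rng = random.Random(config.seed)
    energy_fn = config.search_energy()
    t0 = time.monotonic()
    deadline = t0 + config.time_limit if config.time_limit is not None else None
    pop = initialise(sequence, config.population_size, config.init_max_tries, rng)
    best_conf, best_e = pop.best(energy_fn)
    trace = RunTrace()
    stagnation = 0
    gen_index = 0
    while True:
        if config.max_generations is not None and gen_index >= config.max_generations:
            break
        if deadline is not None and time.monotonic() > deadline:
            break
        pop, op = generation(pop, config, rng, deadline=deadline)
        _, pop_e = pop.best(energy_fn)
        improved = pop_e < best_e
        if improved:
            best_conf, best_e = pop.best(energy_fn)
            stagnation = 0
        else:
            stagnation += 1
        walked = False
        if stagnation >= config.stagnation_window:
            diversified = Population()
            for m in pop:
                diversified.add(random_walk(m, config, rng, deadline=deadline))
            for m in pop:  # re-fill slots lost to de-duplication
                if len(diversified) >= len(pop):
                    break
                diversified.add(m)
            pop = diversified
            stagnation = 0
            walked = True
        energies = [energy_fn(m) for m in pop]
        trace.records.append(
            TraceRecord(
                generation=gen_index,
                operator=op,
                best_energy=best_e,
                population_best=min(energies),
                mean_energy=sum(energies) / len(energies),
                population_size=len(pop),
                stagnation_counter=stagnation,
                random_walk=walked,
            )
        )
        trace.elapsed.append(time.monotonic() - t0)
        gen_index += 1
    return GAResult(best_conf, best_e, trace, config)
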