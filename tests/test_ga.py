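"""GA engine: configs, populations, exhaustive steps, stagnation recovery."""

import random

import pytest

from conftest import grow_random_conformation
from fccfold import ga
from fccfold.benchmarks import (
    enumerate_saws,
    global_minimum,
    random_sequence,
)
from fccfold.conformation import Conformation, energy_bm, energy_hp, validate
from fccfold.ga import (
    ALL_OPERATORS,
    GAConfig,
    Population,
    exhaustive_crossover_step,
    exhaustive_mutation_step,
    fallback_conformation,
    generation,
    initialise,
    random_walk,
    run,
    structural_diversity,
)
from fccfold.moves import diagonal_candidates, rotation_move


def small_config(**kw):
    kw.setdefault("population_size", 6)
    kw.setdefault("max_generations", 10)
    return GAConfig(**kw)


class TestGAConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            GAConfig(population_size=1, max_generations=1)
        with pytest.raises(ValueError):
            GAConfig(variant="XX", max_generations=1)
        with pytest.raises(ValueError):
            GAConfig(energy_band=(0.2, 0.1), max_generations=1)
        with pytest.raises(ValueError):
            GAConfig()  # no termination condition
        with pytest.raises(ValueError):
            GAConfig(max_generations=1, operators=("frobnicate",))
        with pytest.raises(ValueError):
            GAConfig(max_generations=1, weights=(1.0,))

    def test_variant_roster_and_energies(self):
        bh = small_config(variant="BH")
        bm = small_config(variant="BM")
        hp = small_config(variant="HP")
        bd = small_config(variant="BD")
        assert bh.roster() == ALL_OPERATORS
        assert "macro_mutation" not in bm.roster()
        assert hp.search_energy() is energy_hp
        assert bh.search_energy() is energy_bm
        assert bd.macro_guidance() == "bm"
        assert bh.macro_guidance() == hp.macro_guidance() == "hp"


class TestPopulation:
    def test_duplicates_rejected_by_encoding(self, rng):
        seq = random_sequence(8, "20", rng)
        a = grow_random_conformation(seq, rng)
        pop = Population([a])
        assert not pop.add(Conformation.from_encoding(seq, list(a.encoding)))
        assert len(pop) == 1

    def test_best_and_remove_worst(self, rng):
        seq = random_sequence(8, "20", rng)
        members = [grow_random_conformation(seq, rng) for _ in range(8)]
        pop = Population(members)
        best, e = pop.best(energy_bm)
        assert e == min(energy_bm(m) for m in pop)
        assert energy_bm(best) == e
        worst_e = max(energy_bm(m) for m in pop)
        pop.remove_worst(energy_bm)
        assert max(energy_bm(m) for m in pop) <= worst_e
        assert len(pop) == len(members) - 1


class TestInitialise:
    def test_population_contract(self, rng):
        seq = random_sequence(20, "20", rng)
        pop = initialise(seq, 15, 100, rng)
        assert len(pop) == 15
        encs = {m.encoding for m in pop}
        assert len(encs) == 15
        for m in pop:
            assert validate(m)
            assert m.sequence == seq

    def test_zero_tries_uses_fallback_ladder(self, rng):
        pop = initialise("MKYTCAE", 5, 0, rng)
        expected = [fallback_conformation("MKYTCAE", k) for k in range(5)]
        assert [m.encoding for m in pop] == [c.encoding for c in expected]

    def test_fallback_conformations_distinct_and_valid(self):
        seq = "A" * 12
        encs = set()
        for k in range(10):
            conf = fallback_conformation(seq, k)
            assert validate(conf)
            encs.add(conf.encoding)
        assert len(encs) == 10


class TestExhaustiveMutation:
    def test_global_minimum_is_fixed_point(self):
        """At a global optimum no operator can strictly improve, so the
        parent always survives."""
        seq = "FSFSF"
        oracle = global_minimum(seq, "bm")
        conf = oracle.argmin
        cfg = small_config()
        rng = random.Random(0)
        for op in ("rotation", "diagonal", "pull", "tilt", "macro_mutation"):
            child = exhaustive_mutation_step(conf, op, cfg, rng)
            assert child.encoding == conf.encoding

    def test_never_worse_than_parent(self, rng):
        cfg = small_config()
        for _ in range(10):
            conf = grow_random_conformation(random_sequence(12, "20", rng), rng)
            for op in ("rotation", "diagonal", "pull", "tilt"):
                child = exhaustive_mutation_step(conf, op, cfg, rng)
                assert energy_bm(child) <= energy_bm(conf)
                assert validate(child)

    def test_first_improvement_semantics_diagonal(self, rng):
        """Independent first-improvement scan agrees with the engine."""
        cfg = small_config()
        checked = 0
        for _ in range(20):
            conf = grow_random_conformation(random_sequence(12, "20", rng), rng)
            expected = conf
            e0 = energy_bm(conf)
            found = False
            for i in range(1, len(conf) - 1):
                for q in diagonal_candidates(conf, i):
                    coords = list(conf.coords)
                    coords[i] = q
                    cand = Conformation.from_coords(conf.sequence, coords)
                    if energy_bm(cand) < e0:
                        expected = cand
                        found = True
                        break
                if found:
                    break
            got = exhaustive_mutation_step(conf, "diagonal", cfg, rng)
            assert got.encoding == expected.encoding
            checked += found
        assert checked > 0  # at least some strictly-improving scans occurred

    def test_first_improvement_semantics_rotation(self, rng):
        cfg = small_config()
        for _ in range(10):
            conf = grow_random_conformation(random_sequence(10, "20", rng), rng)
            e0 = energy_bm(conf)
            expected = conf
            done = False
            for i in range(1, len(conf) - 1):
                for op in range(1, 10):
                    res = rotation_move(conf, i, op)
                    if res.ok and energy_bm(res.conformation) < e0:
                        expected = res.conformation
                        done = True
                        break
                if done:
                    break
            got = exhaustive_mutation_step(conf, "rotation", cfg, rng)
            assert got.encoding == expected.encoding


class TestExhaustiveCrossover:
    def test_identical_parents_are_returned(self, rng):
        seq = random_sequence(8, "20", rng)
        a = grow_random_conformation(seq, rng)
        c1, c2 = exhaustive_crossover_step(a, a, energy_bm)
        assert c1.encoding == a.encoding
        assert c2.encoding == a.encoding

    def test_returns_two_best_of_pool(self, rng):
        from fccfold.moves import crossover_single_point

        for _ in range(10):
            seq = random_sequence(9, "20", rng)
            a = grow_random_conformation(seq, rng)
            b = grow_random_conformation(seq, rng)
            pool = [a, b]
            for k in range(1, len(seq)):
                for r in crossover_single_point(a, b, k):
                    if r.ok:
                        pool.append(r.conformation)
            want = sorted(energy_bm(c) for c in pool)[:2]
            c1, c2 = exhaustive_crossover_step(a, b, energy_bm)
            assert [energy_bm(c1), energy_bm(c2)] == want
            assert energy_bm(c1) <= min(energy_bm(a), energy_bm(b))


class TestGeneration:
    @pytest.mark.parametrize("operator", ALL_OPERATORS)
    def test_best_never_worsens_and_no_duplicates(self, rng, operator):
        seq = random_sequence(12, "20", rng)
        cfg = small_config(population_size=8)
        pop = initialise(seq, 8, 100, rng)
        _, e_before = pop.best(energy_bm)
        new, used = generation(pop, cfg, rng, operator=operator)
        assert used == operator
        _, e_after = new.best(energy_bm)
        assert e_after <= e_before
        encs = [m.encoding for m in new]
        assert len(encs) == len(set(encs))
        for m in new:
            assert validate(m)


def test_structural_diversity_examples():
    assert structural_diversity((1, 2, 3, 4), (1, 2, 3, 4)) == 0.0
    assert structural_diversity((1, 2, 3, 4), (1, 9, 3, 8)) == 0.5
    assert structural_diversity((), ()) == 0.0
    with pytest.raises(ValueError):
        structural_diversity((1,), (1, 2))


class TestRandomWalk:
    def test_zero_energy_returns_input_untouched(self, rng):
        conf = Conformation.from_encoding("SSSSSS", [1] * 5)
        cfg = small_config()
        assert random_walk(conf, cfg, rng) is conf

    def test_returns_max_diversity_state_inside_both_bands(self, monkeypatch):
        """Scripted walk: the engine must pick, among visited states, the
        one of maximal encoding diversity whose relative energy change lies
        in the energy band."""

        class Fake:
            def __init__(self, enc, e):
                self.encoding = tuple(enc)
                self.e = e

            def __len__(self):
                return len(self.encoding) + 1

        s0 = Fake((1,) * 10, -100.0)
        s1 = Fake((4, 4) + (1,) * 8, -106.0)          # D=0.2, rel=0.06: ok
        s2 = Fake((4,) * 6 + (1,) * 4, -107.0)        # D=0.6, rel=0.07: best
        s3 = Fake((4,) * 7 + (1,) * 3, -50.0)         # energy out of band
        s4 = Fake((4,) * 9 + (1,), -108.0)            # diversity out of band
        script = iter([s1, s2, s3, s4])
        monkeypatch.setattr(
            ga, "_random_pull", lambda conf, rng, tries=64: next(script, None)
        )
        monkeypatch.setattr(
            GAConfig, "search_energy", lambda self: (lambda c: c.e)
        )
        cfg = small_config()
        got = random_walk(s0, cfg, random.Random(0))
        assert got is s2

    def test_no_qualifying_state_returns_input(self, monkeypatch):
        class Fake:
            def __init__(self, enc, e):
                self.encoding = tuple(enc)
                self.e = e

            def __len__(self):
                return len(self.encoding) + 1

        s0 = Fake((1,) * 10, -100.0)
        far = Fake((4,) * 10, -10.0)  # far outside the energy band
        script = iter([far])
        monkeypatch.setattr(
            ga, "_random_pull", lambda conf, rng, tries=64: next(script, None)
        )
        monkeypatch.setattr(
            GAConfig, "search_energy", lambda self: (lambda c: c.e)
        )
        assert random_walk(s0, small_config(), random.Random(0)) is s0


class TestRun:
    def test_reaches_known_hp_optimum_on_tiny_sequence(self):
        seq = "FSFF"
        oracle = global_minimum(seq, "hp")
        cfg = GAConfig(
            population_size=6, variant="HP", max_generations=30, seed=3,
            stagnation_window=5,
        )
        result = run(seq, cfg)
        assert result.best_energy == oracle.min_energy
        assert validate(result.best)

    def test_reaches_known_bm_optimum_n6(self):
        seq = "MKFCYE"
        oracle = global_minimum(seq, "bm")
        cfg = GAConfig(
            population_size=12, variant="BH", max_generations=60, seed=7,
            stagnation_window=10,
        )
        result = run(seq, cfg)
        assert result.best_energy == pytest.approx(oracle.min_energy)

    def test_trace_best_series_monotone_non_increasing(self):
        cfg = GAConfig(
            population_size=8, variant="BH", max_generations=25, seed=11,
            stagnation_window=6,
        )
        result = run("FSFFSFSF", cfg)
        series = result.trace.best_series()
        assert len(series) == 25
        assert all(b <= a for a, b in zip(series, series[1:]))
        assert result.best_energy == series[-1]

    def test_identical_seed_gives_bit_identical_trace(self):
        cfg = GAConfig(
            population_size=8, variant="BH", max_generations=20, seed=42,
            stagnation_window=6,
        )
        r1 = run("FSFFSFSF", cfg)
        r2 = run("FSFFSFSF", cfg)
        assert r1.trace == r2.trace  # elapsed excluded from equality
        assert r1.best.encoding == r2.best.encoding
        assert r1.best_energy == r2.best_energy

    def test_summary_mentions_variant_and_energies(self):
        cfg = GAConfig(population_size=4, max_generations=3, seed=1)
        result = run("FSFF", cfg)
        text = result.summary()
        assert "BH" in text and "E_BM" in text and "E_HP" in text
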