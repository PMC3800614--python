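"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's indexed/incremental code
paths: contacts are found by an O(n^2) all-pairs scan and energies summed
directly from them, so they can arbitrate the fast implementations.
"""

from __future__ import annotations

import random

import pytest

from fccfold.conformation import Conformation
from fccfold.lattice import are_neighbors
from fccfold.residues import bm_energy, is_hydrophobic


def brute_contact_pairs(conf: Conformation) -> list[tuple[int, int]]:
    """All-pairs scan for non-consecutive lattice contacts."""
    n = len(conf)
    return [
        (i, j)
        for i in range(n)
        for j in range(i + 2, n)
        if are_neighbors(conf.coords[i], conf.coords[j])
    ]


def brute_energy_hp(conf: Conformation) -> float:
    return -float(
        sum(
            1
            for i, j in brute_contact_pairs(conf)
            if is_hydrophobic(conf.sequence[i])
            and is_hydrophobic(conf.sequence[j])
        )
    )


def brute_energy_bm(conf: Conformation) -> float:
    return sum(
        bm_energy(conf.sequence[i], conf.sequence[j])
        for i, j in brute_contact_pairs(conf)
    )


def brute_class_counts(conf: Conformation) -> tuple[int, int, int, int]:
    hh = hp = pp = 0
    for i, j in brute_contact_pairs(conf):
        a = is_hydrophobic(conf.sequence[i])
        b = is_hydrophobic(conf.sequence[j])
        if a and b:
            hh += 1
        elif a or b:
            hp += 1
        else:
            pp += 1
    return hh, hp, pp, hh + hp + pp


def grow_random_conformation(
    sequence: str, rng: random.Random, max_tries: int = 1000
) -> Conformation:
    """Random self-avoiding walk carrying ``sequence`` (restart on dead end)."""
    from fccfold.ga import _random_saw

    for _ in range(max_tries):
        conf = _random_saw(sequence, rng)
        if conf is not None:
            return conf
    raise RuntimeError("could not grow a random walk")


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20231)


@pytest.fixture
def random_conformation_factory(rng):
    """Callable (n or sequence) -> random valid conformation."""
    from fccfold.benchmarks import random_sequence

    def make(spec, mode: str = "20") -> Conformation:
        seq = spec if isinstance(spec, str) else random_sequence(spec, mode, rng)
        return grow_random_conformation(seq, rng)

    return make
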