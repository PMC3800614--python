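"""Conformational move operators on FCC self-avoiding walks.

Five primitive operators (single-point crossover, rotation, diagonal, pull,
tilt) plus the hydrophobic-core-directed macro-mutation.  Every operator is a
pure transform: it either returns a new conformation that passes
``validate()`` or reports ``infeasible`` and leaves its input untouched, and
no operator ever alters the amino-acid sequence.

Determinism convention: all "first successful move" scans iterate candidate
displacements in the frozen basis order v1..v12 and residues N-terminus to
C-terminus, so a seeded run is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator, Optional

from . import conformation as cf
from . import lattice
from .conformation import Conformation
from .lattice import BASIS_VECTORS, LatticePoint, are_neighbors
from .residues import hp_class


@dataclass(frozen=True)
class MoveResult:
    """Outcome of a move: a valid new conformation or a typed failure."""

    status: str  # "success" | "infeasible"
    conformation: Optional[Conformation] = None
    descriptor: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "success"


def _success(conf: Conformation, **desc) -> MoveResult:
    return MoveResult("success", conf, desc)


def _infeasible(**desc) -> MoveResult:
    return MoveResult("infeasible", None, desc)


def _try_build(sequence: str, coords) -> Optional[Conformation]:
    """Build a conformation from coordinates, returning None if not a SAW."""
    try:
        return Conformation.from_coords(sequence, coords)
    except (ValueError, lattice.EncodingError):
        return None


# ---------------------------------------------------------------------------
# Diagonal move
# ---------------------------------------------------------------------------

def diagonal_candidates(conf: Conformation, i: int) -> list[LatticePoint]:
    """Free lattice points adjacent to both chain neighbours of residue ``i``.

    Candidates are generated by scanning the 12 neighbours of residue
    ``i - 1`` in frozen basis order; the residue's current position is not a
    candidate.
    """
    a = conf.coords[i - 1]
    c = conf.coords[i + 1]
    occ = conf.occupancy
    return [
        q
        for q in lattice.neighbors(a)
        if q not in occ and are_neighbors(q, c)
    ]


def diagonal_move(
    conf: Conformation,
    i: int,
    accept: Optional[Callable[[LatticePoint], bool]] = None,
) -> MoveResult:
    """Relocate interior residue ``i`` to a free point adjacent to both its
    chain neighbours.

    Candidates are scanned in frozen basis order and the first free candidate
    satisfying the caller's ``accept`` predicate (on the candidate point) is
    taken.  Boundary indices raise ``IndexError``.
    """
    n = len(conf)
    if not 1 <= i <= n - 2:
        raise IndexError(f"diagonal move needs an interior residue, got {i}")
    for q in diagonal_candidates(conf, i):
        if accept is not None and not accept(q):
            continue
        coords = list(conf.coords)
        coords[i] = q
        new = _try_build(conf.sequence, coords)
        if new is not None:
            return _success(new, operator="diagonal", site=i, target=q)
    return _infeasible(operator="diagonal", site=i)


# ---------------------------------------------------------------------------
# Pull move
# ---------------------------------------------------------------------------

def _pull_apply(
    conf: Conformation, i: int, target: LatticePoint, direction: int
) -> Optional[Conformation]:
    """Apply a pull without legality pre-checks; None if the result is invalid."""
    old = list(conf.coords)
    n = len(old)
    new = list(old)
    new[i] = target
    if direction < 0:  # predecessors get dragged
        j = i - 1
        while j >= 0:
            if are_neighbors(old[j], new[j + 1]):
                break
            new[j] = old[j + 1]
            j -= 1
    else:  # successors get dragged
        j = i + 1
        while j < n:
            if are_neighbors(old[j], new[j - 1]):
                break
            new[j] = old[j - 1]
            j += 1
    return _try_build(conf.sequence, new)


def _pull_legal(
    conf: Conformation, i: int, target: LatticePoint, direction: int
) -> bool:
    """Legality of a pull target: free, bonded to the fixed-side neighbour,
    and guaranteed to re-connect (adjacent to the residue's old position or
    to the first dragged neighbour's position)."""
    n = len(conf)
    if target in conf.occupancy:
        return False
    coords = conf.coords
    if direction < 0:
        if i < n - 1 and not are_neighbors(target, coords[i + 1]):
            return False
        if i > 0 and not (
            are_neighbors(target, coords[i])
            or are_neighbors(target, coords[i - 1])
        ):
            return False
    else:
        if i > 0 and not are_neighbors(target, coords[i - 1]):
            return False
        if i < n - 1 and not (
            are_neighbors(target, coords[i])
            or are_neighbors(target, coords[i + 1])
        ):
            return False
    return True


def pull_move(
    conf: Conformation,
    i: int,
    target: LatticePoint,
    direction: Optional[int] = None,
) -> MoveResult:
    """Move residue ``i`` to ``target``, dragging chain neighbours on one side
    through the vacated positions until the walk reconnects.

    ``direction=-1`` drags residues before ``i``; ``+1`` drags those after.
    If omitted, the first legal direction in ``(-1, +1)`` is used.  Successful
    pulls always yield valid self-avoiding walks.
    """
    dirs = (-1, +1) if direction is None else (direction,)
    for d in dirs:
        if _pull_legal(conf, i, target, d):
            new = _pull_apply(conf, i, target, d)
            if new is not None:
                return _success(
                    new, operator="pull", site=i, target=target, direction=d
                )
    return _infeasible(operator="pull", site=i, target=target)


def enumerate_pull_moves(
    conf: Conformation,
) -> Iterator[tuple[int, LatticePoint, int]]:
    """Yield all legal ``(i, target, direction)`` pull triples in frozen order.

    Residues are scanned N->C; for each residue, direction -1 before +1;
    targets scan the 12 neighbours of the fixed-side bond partner (for
    terminal residues, of the residue's single chain neighbour, then of the
    residue itself) in basis order.
    """
    n = len(conf)
    if n < 2:
        return
    coords = conf.coords
    for i in range(n):
        for d in (-1, +1):
            if d == -1:
                anchors = (
                    (coords[i + 1],) if i < n - 1
                    else (coords[i - 1], coords[i])
                )
            else:
                anchors = (
                    (coords[i - 1],) if i > 0
                    else (coords[i + 1], coords[i])
                )
            seen: set[LatticePoint] = set()
            for a in anchors:
                for t in lattice.neighbors(a):
                    if t in seen:
                        continue
                    seen.add(t)
                    if _pull_legal(conf, i, t, d):
                        yield i, t, d


# ---------------------------------------------------------------------------
# Tilt move
# ---------------------------------------------------------------------------

def collinear_run(conf: Conformation, i: int) -> tuple[int, int]:
    """Maximal run ``[i..j]`` of residues collinear along one basis vector,
    starting at residue ``i`` (so steps i..j-1 are all equal).

    Raises ``IndexError`` if ``i`` is the last residue (no step starts there).
    """
    n = len(conf)
    if not 0 <= i <= n - 2:
        raise IndexError(f"no collinear run starting at residue {i}")
    enc = conf.encoding
    j = i + 1
    while j <= n - 2 and enc[j] == enc[i]:
        j += 1
    return i, j


def tilt_move(conf: Conformation, i: int) -> MoveResult:
    """Translate the maximal straight run starting at residue ``i`` to an
    immediately parallel lattice line, re-attaching both flanks by pulling
    them through vacated positions.

    The run is shifted by a basis vector orthogonal to the run direction
    (candidates scanned in frozen basis order); the move is infeasible if no
    shift yields a valid walk.
    """
    a, b = collinear_run(conf, i)
    old = conf.coords
    d = BASIS_VECTORS[conf.encoding[a] - 1]
    for t in BASIS_VECTORS:
        if t[0] * d[0] + t[1] * d[1] + t[2] * d[2] != 0:
            continue
        shifted = [
            (old[k][0] + t[0], old[k][1] + t[1], old[k][2] + t[2])
            for k in range(a, b + 1)
        ]
        if any(p in conf.occupancy for p in shifted):
            continue
        new = list(old)
        new[a : b + 1] = shifted
        # re-attach the N-side flank
        j = a - 1
        while j >= 0:
            if are_neighbors(old[j], new[j + 1]):
                break
            new[j] = old[j + 1]
            j -= 1
        # re-attach the C-side flank
        j = b + 1
        n = len(old)
        while j < n:
            if are_neighbors(old[j], new[j - 1]):
                break
            new[j] = old[j - 1]
            j += 1
        built = _try_build(conf.sequence, new)
        if built is not None:
            return _success(built, operator="tilt", site=a, run=(a, b), shift=t)
    return _infeasible(operator="tilt", site=a, run=(a, b))


# ---------------------------------------------------------------------------
# Rotation move
# ---------------------------------------------------------------------------

def _rot_matrices() -> tuple[tuple[tuple[int, ...], ...], ...]:
    """Identity plus the nine 90/180/270-degree rotations about x, y, z.

    These signed permutations map the FCC basis set onto itself, so rotating
    a chain segment keeps it on the lattice.
    """

    def rx(c, s):
        return ((1, 0, 0), (0, c, -s), (0, s, c))

    def ry(c, s):
        return ((c, 0, s), (0, 1, 0), (-s, 0, c))

    def rz(c, s):
        return ((c, -s, 0), (s, c, 0), (0, 0, 1))

    mats = [((1, 0, 0), (0, 1, 0), (0, 0, 1))]
    for maker in (rx, ry, rz):
        for c, s in ((0, 1), (-1, 0), (0, -1)):  # 90, 180, 270 degrees
            mats.append(maker(c, s))
    return tuple(mats)


#: Frozen rotation set: index 0 is the identity, 1..9 the axis rotations.
ROTATIONS = _rot_matrices()


def rotation_move(conf: Conformation, i: int, op: int) -> MoveResult:
    """Rotate the tail ``i+1..n-1`` about residue ``i`` by ``ROTATIONS[op]``.

    Succeeds iff the rotated chain is still a self-avoiding walk.
    """
    n = len(conf)
    if not 1 <= i <= n - 2:
        raise IndexError(f"rotation pivot must be interior, got {i}")
    m = ROTATIONS[op]
    px, py, pz = conf.coords[i]
    new = list(conf.coords)
    for j in range(i + 1, n):
        x, y, z = conf.coords[j]
        dx, dy, dz = x - px, y - py, z - pz
        new[j] = (
            px + m[0][0] * dx + m[0][1] * dy + m[0][2] * dz,
            py + m[1][0] * dx + m[1][1] * dy + m[1][2] * dz,
            pz + m[2][0] * dx + m[2][1] * dy + m[2][2] * dz,
        )
    built = _try_build(conf.sequence, new)
    if built is None:
        return _infeasible(operator="rotation", site=i, op=op)
    return _success(built, operator="rotation", site=i, op=op)


# ---------------------------------------------------------------------------
# Crossover
# ---------------------------------------------------------------------------

def crossover_single_point(
    a: Conformation, b: Conformation, k: int
) -> tuple[MoveResult, MoveResult]:
    """Exchange encoding tails of two parents at split index ``k``.

    ``k`` indexes the relative encoding (1 <= k <= n-1); each child is decoded
    and validated independently, and either may be infeasible.
    """
    n = len(a)
    if len(b) != n:
        raise ValueError("parents must have equal length")
    if not 1 <= k <= n - 1:
        raise IndexError(f"split index {k} outside 1..{n - 1}")
    out = []
    for head, tail, seq in (
        (a.encoding[:k], b.encoding[k:], a.sequence),
        (b.encoding[:k], a.encoding[k:], b.sequence),
    ):
        child = _try_build_encoding(seq, head + tail)
        if child is None:
            out.append(_infeasible(operator="crossover", site=k))
        else:
            out.append(_success(child, operator="crossover", site=k))
    return out[0], out[1]


def _try_build_encoding(sequence: str, enc) -> Optional[Conformation]:
    try:
        return Conformation.from_encoding(sequence, enc)
    except (ValueError, lattice.EncodingError):
        return None


# ---------------------------------------------------------------------------
# Macro-mutation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MacroMutationParams:
    """Knobs of the core-directed macro-mutation.

    ``p`` is the Bernoulli probability of targeting polar residues in a given
    call (hydrophobic residues are targeted with probability ``1 - p``);
    ``repeat`` is the number of full chain traversals applied as one
    composite move.
    """

    p: float = 0.2
    repeat: int = 2

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0, 1]")
        if self.repeat < 1:
            raise ValueError("repeat must be >= 1")


def macro_mutation(
    conf: Conformation,
    params: MacroMutationParams,
    rng,
    guidance: str = "hp",
    energy_fn: Optional[Callable[[Conformation], float]] = None,
) -> MoveResult:
    """Composite operator squeezing the hydrophobic core with diagonal moves.

    One Bernoulli draw per call picks the residue class to traverse: polar
    with probability ``p``, hydrophobic otherwise.  The chain is traversed
    N->C; at each interior residue of the chosen class the first successful
    diagonal move is applied — for hydrophobic residues only if it does not
    increase the (squared Euclidean) distance to the hydrophobic core centre,
    which is recomputed after every accepted relocation.  The traversal is
    repeated ``params.repeat`` times and the accepted relocations form one
    composite move; with no applicable move the input is returned unchanged.

    ``guidance="bm"`` replaces the core-distance test with an energy test
    (accept the first diagonal move that does not worsen ``energy_fn``),
    giving the potential-guided ablation variant of the operator.
    """
    if guidance not in ("hp", "bm"):
        raise ValueError(f"unknown guidance {guidance!r}")
    if guidance == "bm" and energy_fn is None:
        raise ValueError("bm guidance needs an energy function")
    target_class = "P" if rng.random() < params.p else "H"
    work = conf
    n = len(conf)
    moved: list[int] = []
    for _ in range(params.repeat):
        for i in range(1, n - 1):
            if hp_class(work.sequence[i]) != target_class:
                continue
            if guidance == "hp":
                if target_class == "H":
                    s, nh = cf.hcc_sum_count(work)
                    cur = work.coords[i]
                    d_old = _sq_num(cur, s, nh)
                    res = diagonal_move(
                        work, i, accept=lambda q: _sq_num(q, s, nh) <= d_old
                    )
                else:
                    res = diagonal_move(work, i)
                if res.ok:
                    work = res.conformation
                    moved.append(i)
            else:  # energy-guided variant
                e0 = energy_fn(work)
                for q in diagonal_candidates(work, i):
                    coords = list(work.coords)
                    coords[i] = q
                    cand = _try_build(work.sequence, coords)
                    if cand is not None and energy_fn(cand) <= e0:
                        work = cand
                        moved.append(i)
                        break
    return _success(work, operator="macro_mutation", cls=target_class,
                    moved=tuple(moved))


def _sq_num(p: LatticePoint, s: tuple[int, int, int], nh: int) -> int:
    """Integer numerator of the squared distance from ``p`` to the HCC."""
    dx = nh * p[0] - s[0]
    dy = nh * p[1] - s[1]
    dz = nh * p[2] - s[2]
    return dx * dx + dy * dy + dz * dz
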