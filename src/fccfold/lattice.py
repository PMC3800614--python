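"""Geometry of the 3D face-centred-cubic (FCC) lattice.

Every lattice site has 12 nearest neighbours reached by the basis vectors
``v1..v12``.  The ordering of the basis set is frozen package-wide: every
"first successful move" scan in the search iterates candidates in this order,
which makes runs with a fixed seed bit-reproducible.

All geometry is exact integer arithmetic: a lattice point is a plain
``(x, y, z)`` tuple of Python ints, so self-avoidance checks are bit-exact.
"""

from __future__ import annotations

from typing import Iterable, Sequence

LatticePoint = tuple[int, int, int]

#: The 12 FCC basis vectors in their frozen order.  Each has two +/-1
#: components and one 0 component (squared norm 2), and the set is closed
#: under negation, so every walk can be traversed in reverse.
BASIS_VECTORS: tuple[LatticePoint, ...] = (
    (1, 1, 0),    # v1
    (-1, -1, 0),  # v2
    (-1, 1, 0),   # v3
    (1, -1, 0),   # v4
    (0, 1, 1),    # v5
    (0, 1, -1),   # v6
    (1, 0, 1),    # v7
    (1, 0, -1),   # v8
    (0, -1, 1),   # v9
    (-1, 0, 1),   # v10
    (0, -1, -1),  # v11
    (-1, 0, -1),  # v12
)

#: 1-based basis index for each displacement vector.
VECTOR_INDEX: dict[LatticePoint, int] = {
    v: i + 1 for i, v in enumerate(BASIS_VECTORS)
}

_BASIS_SET = frozenset(BASIS_VECTORS)


class EncodingError(ValueError):
    """Raised when a coordinate chain cannot be expressed as basis steps."""


def neighbors(p: LatticePoint) -> list[LatticePoint]:
    """Return the 12 lattice neighbours of ``p`` in frozen basis order."""
    x, y, z = p
    return [(x + dx, y + dy, z + dz) for dx, dy, dz in BASIS_VECTORS]


def are_neighbors(a: LatticePoint, b: LatticePoint) -> bool:
    """True iff ``b - a`` is one of the 12 basis vectors."""
    return (b[0] - a[0], b[1] - a[1], b[2] - a[2]) in _BASIS_SET


def encode(coords: Sequence[LatticePoint]) -> tuple[int, ...]:
    """Express a chain of lattice points as 1-based basis-vector indices.

    The encoding is absolute (each step is a basis vector, not a turn
    relative to the previous step) and translation-invariant; decoding from
    the origin reproduces ``coords`` translated to start at ``(0, 0, 0)``.

    Raises
    ------
    EncodingError
        If two consecutive points are not lattice neighbours.
    """
    steps = []
    for k in range(1, len(coords)):
        a, b = coords[k - 1], coords[k]
        d = (b[0] - a[0], b[1] - a[1], b[2] - a[2])
        idx = VECTOR_INDEX.get(d)
        if idx is None:
            raise EncodingError(
                f"points {a} and {b} at positions {k - 1},{k} are not lattice "
                f"neighbours (step {d})"
            )
        steps.append(idx)
    return tuple(steps)


def decode(enc: Iterable[int]) -> list[LatticePoint]:
    """Rebuild coordinates from basis indices, starting at the origin.

    Self-avoidance is *not* checked here; the caller validates.  An empty
    encoding decodes to the single point ``(0, 0, 0)``.
    """
    x, y, z = 0, 0, 0
    coords: list[LatticePoint] = [(0, 0, 0)]
    for idx in enc:
        if not 1 <= idx <= 12:
            raise EncodingError(f"basis index {idx} outside 1..12")
        dx, dy, dz = BASIS_VECTORS[idx - 1]
        x, y, z = x + dx, y + dy, z + dz
        coords.append((x, y, z))
    return coords


def translate_to_origin(coords: Sequence[LatticePoint]) -> list[LatticePoint]:
    """Rigidly translate a chain so its first point is the origin."""
    x0, y0, z0 = coords[0]
    if (x0, y0, z0) == (0, 0, 0):
        return list(coords)
    return [(x - x0, y - y0, z - z0) for x, y, z in coords]
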