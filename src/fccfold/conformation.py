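"""Conformations: self-avoiding walks on the FCC lattice carrying a protein
sequence, plus contact enumeration and the HP / BM energy functions.

A conformation stores four mutually consistent views of the same structure:
the amino-acid sequence, absolute integer coordinates anchored at the origin,
the relative (basis-vector) encoding, and an occupancy index mapping lattice
points back to residue positions.  The occupancy index makes contact
enumeration O(12 n) instead of the O(n^2) all-pairs scan (which remains the
test oracle).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

from . import lattice
from .lattice import LatticePoint
from .residues import bm_energy, hp_class, is_hydrophobic, validate_sequence


@dataclass(frozen=True)
class Contact:
    """A non-consecutive lattice contact between residues i < j - 1 (0-based)."""

    i: int
    j: int
    kind: str  # "HH", "HP" or "PP"


@dataclass(frozen=True)
class Conformation:
    sequence: str
    coords: tuple[LatticePoint, ...]
    encoding: tuple[int, ...] = field(compare=False)
    occupancy: dict[LatticePoint, int] = field(compare=False, repr=False)

    def __len__(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_coords(
        cls, sequence: str, coords: Sequence[LatticePoint]
    ) -> "Conformation":
        """Build a conformation from coordinates, re-anchoring at the origin.

        Raises on length mismatch, bad residue letters, non-adjacent steps or
        revisited lattice points.
        """
        validate_sequence(sequence)
        if len(sequence) != len(coords):
            raise ValueError(
                f"sequence length {len(sequence)} != {len(coords)} coordinates"
            )
        anchored = tuple(lattice.translate_to_origin(coords))
        enc = lattice.encode(anchored)
        occ = {p: i for i, p in enumerate(anchored)}
        if len(occ) != len(anchored):
            raise ValueError("walk revisits a lattice point (not self-avoiding)")
        return cls(sequence, anchored, enc, occ)

    @classmethod
    def from_encoding(cls, sequence: str, enc: Iterable[int]) -> "Conformation":
        """Decode a basis-index string into a conformation (validating SAW)."""
        return cls.from_coords(sequence, lattice.decode(enc))

    # -- serialisation ----------------------------------------------------

    def to_record(self) -> dict:
        return {
            "sequence": self.sequence,
            "encoding": ",".join(map(str, self.encoding)),
            "coords": [list(p) for p in self.coords],
        }

    @classmethod
    def from_record(cls, record: dict) -> "Conformation":
        enc_str = record["encoding"]
        enc = [int(s) for s in enc_str.split(",")] if enc_str else []
        return cls.from_encoding(record["sequence"], enc)

    def to_json(self) -> str:
        return json.dumps(self.to_record())


def read_fasta_sequence(path) -> str:
    """Read a single-record FASTA file and return its residue string."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, got {len(records)}")
    seq = str(records[0].seq).upper()
    validate_sequence(seq)
    return seq


def validate(conf: Conformation) -> bool:
    """True iff ``conf`` is a consistent self-avoiding walk.

    Checks chain connectivity, coordinate distinctness, occupancy/encoding
    consistency and sequence/coordinate length agreement.  Returns ``False``
    rather than raising.
    """
    n = len(conf.sequence)
    if len(conf.coords) != n or n == 0:
        return False
    if len(set(conf.coords)) != n:
        return False
    for k in range(1, n):
        if not lattice.are_neighbors(conf.coords[k - 1], conf.coords[k]):
            return False
    if conf.occupancy != {p: i for i, p in enumerate(conf.coords)}:
        return False
    try:
        if lattice.encode(conf.coords) != conf.encoding:
            return False
    except lattice.EncodingError:
        return False
    return True


def contacts(conf: Conformation) -> list[Contact]:
    """Enumerate non-consecutive lattice contacts via the occupancy index.

    For each residue the 12 neighbouring points are probed in the occupancy
    map; pairs with j > i + 1 are kept.  Equals the O(n^2) all-pairs scan.
    """
    occ = conf.occupancy
    seq = conf.sequence
    out: list[Contact] = []
    for i, p in enumerate(conf.coords):
        for q in lattice.neighbors(p):
            j = occ.get(q)
            if j is not None and j > i + 1:
                ci, cj = hp_class(seq[i]), hp_class(seq[j])
                kind = "HH" if ci == cj == "H" else (
                    "PP" if ci == cj == "P" else "HP"
                )
                out.append(Contact(i, j, kind))
    return out


def energy_hp(conf: Conformation) -> float:
    """HP-model energy: -1 per non-consecutive H-H lattice contact."""
    occ = conf.occupancy
    hyd = [is_hydrophobic(aa) for aa in conf.sequence]
    e = 0
    for i, (x, y, z) in enumerate(conf.coords):
        if not hyd[i]:
            continue
        for dx, dy, dz in lattice.BASIS_VECTORS:
            j = occ.get((x + dx, y + dy, z + dz))
            if j is not None and j > i + 1 and hyd[j]:
                e -= 1
    return float(e)


def energy_bm(conf: Conformation) -> float:
    """Contact-potential energy: sum of pair energies over all contacts."""
    occ = conf.occupancy
    seq = conf.sequence
    e = 0.0
    for i, (x, y, z) in enumerate(conf.coords):
        for dx, dy, dz in lattice.BASIS_VECTORS:
            j = occ.get((x + dx, y + dy, z + dz))
            if j is not None and j > i + 1:
                e += bm_energy(seq[i], seq[j])
    return e


def contact_class_counts(conf: Conformation) -> tuple[int, int, int, int]:
    """Return ``(HH, HP, PP, total)`` contact counts; classes partition total."""
    hh = hp = pp = 0
    for c in contacts(conf):
        if c.kind == "HH":
            hh += 1
        elif c.kind == "HP":
            hp += 1
        else:
            pp += 1
    return hh, hp, pp, hh + hp + pp


def hydrophobic_core_center(conf: Conformation) -> tuple[float, float, float]:
    """Arithmetic mean of the coordinates of all hydrophobic residues (HCC)."""
    pts = [p for aa, p in zip(conf.sequence, conf.coords) if is_hydrophobic(aa)]
    if not pts:
        raise ValueError("sequence has no hydrophobic residues; HCC undefined")
    n = len(pts)
    return (
        sum(p[0] for p in pts) / n,
        sum(p[1] for p in pts) / n,
        sum(p[2] for p in pts) / n,
    )


def hcc_sum_count(conf: Conformation) -> tuple[tuple[int, int, int], int]:
    """Integer coordinate sum and count of H residues (exact HCC arithmetic).

    Distance-to-HCC comparisons use ``|n_H * p - S|^2`` in integers, which
    orders points by squared Euclidean distance to the (rational) HCC without
    any floating point.
    """
    sx = sy = sz = 0
    n = 0
    for aa, p in zip(conf.sequence, conf.coords):
        if is_hydrophobic(aa):
            sx += p[0]
            sy += p[1]
            sz += p[2]
            n += 1
    if n == 0:
        raise ValueError("sequence has no hydrophobic residues; HCC undefined")
    return (sx, sy, sz), n


def squared_distance_to_hcc(
    point: LatticePoint, hcc_sum: tuple[int, int, int], n_h: int
) -> Fraction:
    """Exact squared Euclidean distance from ``point`` to the HCC."""
    dx = n_h * point[0] - hcc_sum[0]
    dy = n_h * point[1] - hcc_sum[1]
    dz = n_h * point[2] - hcc_sum[2]
    return Fraction(dx * dx + dy * dy + dz * dz, n_h * n_h)
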