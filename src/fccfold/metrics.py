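"""Evaluation machinery: distance-matrix RMSD, relative improvement,
contact tables, progress curves and a Mann-Whitney U utility.

The RMSD used here is the superposition-free distance-matrix form

    dRMSD = sqrt( sum_{i<j} (d_ij^p - d_ij^n)^2 / (n(n-1)/2) )

over all residue pairs, where d^p and d^n are pairwise Calpha distances in
the predicted and native structure.  Lattice conformations are mapped to
Angstroms so that one basis-vector step (Euclidean length sqrt(2) in lattice
units) equals 3.8 A, the mean Calpha-Calpha distance.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .conformation import Conformation

#: Angstroms per lattice *coordinate* unit: a basis step has Euclidean
#: length sqrt(2), and one step is taken as 3.8 A.
ANGSTROM_PER_UNIT = 3.8 / math.sqrt(2.0)


def pairwise_distances(coords: np.ndarray) -> np.ndarray:
    """Symmetric n x n Euclidean distance matrix of an (n, 3) array."""
    coords = np.asarray(coords, dtype=float)
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff * diff).sum(axis=-1))


def lattice_to_angstrom(conf: Conformation) -> np.ndarray:
    """Pairwise distance matrix of a lattice conformation, in Angstroms."""
    return pairwise_distances(np.array(conf.coords)) * ANGSTROM_PER_UNIT


def drmsd(pred: np.ndarray, native: np.ndarray) -> float:
    """Distance-matrix RMSD between two n x n distance matrices (Angstroms)."""
    pred = np.asarray(pred, dtype=float)
    native = np.asarray(native, dtype=float)
    if pred.shape != native.shape or pred.ndim != 2 or pred.shape[0] < 2:
        raise ValueError(
            f"need two equal n x n matrices with n >= 2, got "
            f"{pred.shape} and {native.shape}"
        )
    n = pred.shape[0]
    iu = np.triu_indices(n, k=1)
    diff = pred[iu] - native[iu]
    return float(np.sqrt((diff * diff).sum() / (n * (n - 1) / 2)))


def drmsd_to_native(conf: Conformation, native_ca: np.ndarray) -> float:
    """dRMSD of a lattice conformation against native Calpha coordinates.

    Residue correspondence is positional (1:1 by index).
    """
    native_ca = np.asarray(native_ca, dtype=float)
    if native_ca.shape != (len(conf), 3):
        raise ValueError(
            f"native coordinates shape {native_ca.shape} does not match "
            f"sequence length {len(conf)}"
        )
    return drmsd(lattice_to_angstrom(conf), pairwise_distances(native_ca))


def read_ca_coords(pdb_path, chain_id: Optional[str] = None) -> np.ndarray:
    """Extract the Calpha trace of one chain from a PDB file (Angstroms)."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("native", str(pdb_path))
    model = next(structure.get_models())
    chains = list(model.get_chains())
    if chain_id is not None:
        chains = [c for c in chains if c.id == chain_id]
        if not chains:
            raise ValueError(f"chain {chain_id!r} not found")
    chain = chains[0]
    coords = [
        res["CA"].get_coord()
        for res in chain.get_residues()
        if "CA" in res
    ]
    if not coords:
        raise ValueError("no Calpha atoms found")
    return np.array(coords, dtype=float)


def relative_improvement(e_target: float, e_reference: float) -> float:
    """Relative improvement of a target over a reference, in percent:
    ``(E_t - E_r) / E_r * 100``.

    For energies the signed formula is returned directly (improvements of
    negative energies come out positive); for RMSD comparisons callers
    conventionally report the absolute value.
    """
    if e_reference == 0:
        raise ZeroDivisionError("reference value must be nonzero")
    return (e_target - e_reference) / e_reference * 100.0


def mann_whitney_u(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float]:
    """Rank-sum U statistic of sample_a and a two-sided p-value from the
    tie-corrected normal approximation."""
    if len(sample_a) == 0 or len(sample_b) == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.mannwhitneyu(
        sample_a, sample_b, alternative="two-sided", method="asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def progress_summary(
    traces: Sequence, interval: int
) -> list[tuple[int, float]]:
    """Mean best-so-far energy per generation interval across several runs.

    ``traces`` are :class:`~fccfold.ga.RunTrace` objects (or anything with a
    ``best_series()``).  Each series is sampled at the end of every
    ``interval`` generations, carrying its last value forward when a run
    ended early; returns ``(generation, mean best-so-far)`` rows suitable for
    a progress plot.
    """
    if not traces:
        raise ValueError("need at least one trace")
    if interval < 1:
        raise ValueError("interval must be >= 1")
    series = [t.best_series() for t in traces]
    longest = max(len(s) for s in series)
    if longest == 0:
        raise ValueError("traces are empty")
    rows = []
    for end in range(interval - 1, longest + interval - 1, interval):
        vals = [s[min(end, len(s) - 1)] for s in series]
        rows.append((min(end, longest - 1), sum(vals) / len(vals)))
    return rows
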