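"""Rigid-body superposition of cell vertex sets and the database scan.

Two P1 cells are compared by superposing their four vertex points
(origin plus the three axis endpoints) with the least-squares optimal
proper rotation and translation (the Kabsch solution), and taking the
minimum RMSD over the six right-handed axis assignments of the candidate
cell.  Proteins are enantiomorphic, so improper (mirror) superpositions
are never considered: each permuted candidate is re-orthogonalized with
the fixed right-handed convention, which generates exactly six proper
candidates and no mirror images.

A candidate within the cutoff — the larger of 2.5 Å or 1% of the sum of
the longest and shortest dimension of the query cell as supplied — is a
positive match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .cell_geometry import UnitCell, cell_vertices, validate_cell
from .reduction import P1Cell

if TYPE_CHECKING:  # pragma: no cover
    from .database import Database, EntryRecord

#: Fixed order of the six axis assignments: identity first, then lexicographic.
AXIS_PERMUTATIONS: tuple[tuple[int, int, int], ...] = (
    (0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0),
)

CUTOFF_FLOOR = 2.5  # Å
CUTOFF_FRACTION = 0.01


@dataclass(frozen=True)
class SuperpositionResult:
    rmsd: float
    rotation: np.ndarray
    translation: np.ndarray
    permutation: tuple[int, int, int] = (0, 1, 2)


@dataclass(frozen=True)
class MatchHit:
    """One database entry whose reduced P1 cell matched the query."""

    entry_id: str
    rmsd: float
    permutation: tuple[int, int, int]
    record: "EntryRecord" = field(repr=False)


def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> SuperpositionResult:
    """Optimal proper-rotation superposition of P onto Q (corresponding rows).

    Centroids are superposed (the fit includes a translation); the rotation
    is the SVD solution with the determinant sign corrected so that only
    proper rotations are returned.  RMSD is sqrt(mean squared residual).
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"point sets must have matching Nx3 shapes, got {P.shape} and {Q.shape}")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T  # rotates P0 rows: (R @ P0.T).T
    diff = P0 @ R.T - Q0
    rmsd = float(np.sqrt((diff * diff).sum() / P.shape[0]))
    t = qc - R @ pc
    return SuperpositionResult(rmsd=rmsd, rotation=R, translation=t)


def axis_permutations(cell: UnitCell) -> list[UnitCell]:
    """The six right-handed relabellings of a cell's axes.

    Each permutation acts jointly on the (length, opposite-angle) pairs
    (a, alpha), (b, beta), (c, gamma); the permuted parameter set is later
    re-orthogonalized with the right-handed convention, so no mirror image
    is ever produced.
    """
    validate_cell(cell)
    lengths, angles = cell.lengths, cell.angles
    return [
        UnitCell(
            lengths[p[0]], lengths[p[1]], lengths[p[2]],
            angles[p[0]], angles[p[1]], angles[p[2]],
        )
        for p in AXIS_PERMUTATIONS
    ]


def best_cell_rmsd(query: UnitCell, candidate: UnitCell) -> SuperpositionResult:
    """Minimum-RMSD superposition over the six axis assignments.

    Ties are broken by the first permutation in ``AXIS_PERMUTATIONS``
    (identity first, then lexicographic), making the result deterministic.
    """
    qv = cell_vertices(query).as_array()
    best: SuperpositionResult | None = None
    for perm, permuted in zip(AXIS_PERMUTATIONS, axis_permutations(candidate)):
        res = kabsch_superpose(cell_vertices(permuted).as_array(), qv)
        if best is None or res.rmsd < best.rmsd:
            best = SuperpositionResult(
                rmsd=res.rmsd, rotation=res.rotation,
                translation=res.translation, permutation=perm,
            )
    assert best is not None
    return best


def default_cutoff(query: UnitCell) -> float:
    """max(2.5 Å, 1% of (longest + shortest dimension)) of the query cell.

    The dimensions are those of the query cell exactly as supplied, before
    any reduction.
    """
    validate_cell(query)
    return max(CUTOFF_FLOOR, CUTOFF_FRACTION * (max(query.lengths) + min(query.lengths)))


def scan_database(query_p1: P1Cell, db: "Database", cutoff: float) -> list[MatchHit]:
    """All database entries whose reduced P1 cell superposes within *cutoff*.

    Hits are sorted by ascending RMSD with entry_id as tie-break, so the
    result is independent of storage or scan order.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    hits: list[MatchHit] = []
    for record in db.entries.values():
        res = best_cell_rmsd(query_p1.cell, record.p1_cell.cell)
        if res.rmsd <= cutoff:
            hits.append(
                MatchHit(
                    entry_id=record.entry_id, rmsd=res.rmsd,
                    permutation=res.permutation, record=record,
                )
            )
    hits.sort(key=lambda h: (h.rmsd, h.entry_id))
    return hits
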