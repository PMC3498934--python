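"""Reduction of any (cell, space group) pair to a canonical primitive P1 cell.

Two steps, both deterministic:

1. *Centering removal* — a centered conventional cell (A, B, C, I, F or the
   hexagonal setting of a rhombohedral lattice) contains 2-4 lattice
   points; a fixed standard transformation maps its basis to a primitive
   basis of the same lattice, shrinking the volume by the centering
   multiplicity.

2. *Niggli reduction* — the Křivý-Gruber (1976) iteration brings the
   primitive basis to the unique Niggli-reduced form, a canonical cell of
   the lattice independent of how the lattice was originally described.
   Comparisons use an epsilon scaled to the squared cell edges so the
   iteration is stable against floating-point noise.

The resulting P1 cell is what queries and database entries are compared
on; canonicalizing both sides makes the later superposition meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cell_geometry import UnitCell, basis_to_cell, cell_to_basis, validate_cell
from .errors import ReductionError
from .spacegroup import SpaceGroupInfo, parse_space_group

__all__ = [
    "P1Cell",
    "centering_transform",
    "primitive_cell",
    "niggli_reduce",
    "reduce_to_p1",
    "parse_space_group",
]

#: Rows express the primitive basis vectors in the conventional basis.
#: One fixed standard choice per centering type; after Niggli
#: canonicalization the particular choice is immaterial.
_CENTERING_MATRICES: dict[str, np.ndarray] = {
    "P": np.eye(3),
    "R_rhomb": np.eye(3),
    "A": np.array([[1, 0, 0], [0, 0.5, 0.5], [0, -0.5, 0.5]]),
    "B": np.array([[0.5, 0, 0.5], [0, 1, 0], [-0.5, 0, 0.5]]),
    "C": np.array([[0.5, 0.5, 0], [-0.5, 0.5, 0], [0, 0, 1]]),
    "I": np.array([[-0.5, 0.5, 0.5], [0.5, -0.5, 0.5], [0.5, 0.5, -0.5]]),
    "F": np.array([[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]]),
    "R_hex": np.array(
        [[2 / 3, 1 / 3, 1 / 3], [-1 / 3, 1 / 3, 1 / 3], [-1 / 3, -2 / 3, 1 / 3]]
    ),
}

NIGGLI_EPS_SCALE = 1e-5
NIGGLI_MAX_STEPS = 1000


@dataclass(frozen=True)
class P1Cell:
    """A canonical primitive cell with provenance."""

    cell: UnitCell
    source_cell: UnitCell
    source_space_group: str


def centering_transform(centering: str) -> np.ndarray:
    """3x3 conventional-to-primitive transformation for a centering type.

    ``|det| = 1 / multiplicity``; P and the rhombohedral setting are already
    primitive and return the identity.
    """
    try:
        return _CENTERING_MATRICES[centering].copy()
    except KeyError:
        raise ValueError(f"unknown centering type {centering!r}") from None


def primitive_cell(cell: UnitCell, sg: SpaceGroupInfo) -> UnitCell:
    """Cell parameters of the primitive basis for (cell, space group)."""
    if sg.centering in ("P", "R_rhomb"):
        return validate_cell(cell)  # already primitive
    basis = cell_to_basis(validate_cell(cell))
    prim = centering_transform(sg.centering) @ basis
    return basis_to_cell(prim)


def _niggli_params(cell: UnitCell) -> tuple[float, float, float, float, float, float]:
    a, b, c = cell.lengths
    al, be, ga = (math.radians(x) for x in cell.angles)
    return (
        a * a,
        b * b,
        c * c,
        2.0 * b * c * math.cos(al),
        2.0 * a * c * math.cos(be),
        2.0 * a * b * math.cos(ga),
    )


def _cell_from_niggli_params(
    A: float, B: float, C: float, xi: float, eta: float, zeta: float
) -> UnitCell:
    a, b, c = math.sqrt(A), math.sqrt(B), math.sqrt(C)
    al = math.degrees(math.acos(max(-1.0, min(1.0, xi / (2.0 * b * c)))))
    be = math.degrees(math.acos(max(-1.0, min(1.0, eta / (2.0 * a * c)))))
    ga = math.degrees(math.acos(max(-1.0, min(1.0, zeta / (2.0 * a * b)))))
    return validate_cell(UnitCell(a, b, c, al, be, ga))


def niggli_reduce(cell: UnitCell) -> UnitCell:
    """Niggli-reduce a cell with the Křivý-Gruber iteration.

    Returns the canonical reduced cell of the same lattice (a <= b <= c and
    the Niggli angle conditions hold; volume is preserved).  Raises
    :class:`ReductionError` if the iteration fails to settle within
    ``NIGGLI_MAX_STEPS`` — a sign of pathological input.
    """
    validate_cell(cell)
    A, B, C, xi, eta, zeta = _niggli_params(cell)
    eps = 0.0

    def gt(x: float, y: float) -> bool:
        return x > y + eps

    def lt(x: float, y: float) -> bool:
        return x < y - eps

    def eq(x: float, y: float) -> bool:
        return abs(x - y) <= eps

    for _ in range(NIGGLI_MAX_STEPS):
        # comparisons tolerate FP noise at the scale of the current cell;
        # recomputed per pass because the edges shrink as reduction proceeds
        eps = NIGGLI_EPS_SCALE * (A + B + C) / 3.0
        # step 1: order A <= B
        if gt(A, B) or (eq(A, B) and gt(abs(xi), abs(eta))):
            A, B, xi, eta = B, A, eta, xi
        # step 2: order B <= C
        if gt(B, C) or (eq(B, C) and gt(abs(eta), abs(zeta))):
            B, C, eta, zeta = C, B, zeta, eta
            continue
        # steps 3/4: fix the signs of (xi, eta, zeta)
        l = 1 if gt(xi, 0.0) else (-1 if lt(xi, 0.0) else 0)
        m = 1 if gt(eta, 0.0) else (-1 if lt(eta, 0.0) else 0)
        n = 1 if gt(zeta, 0.0) else (-1 if lt(zeta, 0.0) else 0)
        if l * m * n == 1:
            xi, eta, zeta = abs(xi), abs(eta), abs(zeta)
        else:
            # make all non-positive with an even number of sign flips
            flips = [1, 1, 1]
            free = -1
            for i, s in enumerate((l, m, n)):
                if s == 1:
                    flips[i] = -1
                elif s == 0:
                    free = i
            if flips[0] * flips[1] * flips[2] == -1:
                flips[free] = -1
            xi, eta, zeta = xi * flips[0], eta * flips[1], zeta * flips[2]
        # step 5: |xi| <= B
        if gt(abs(xi), B) or (eq(xi, B) and lt(2 * eta, zeta)) or (
            eq(xi, -B) and lt(zeta, 0.0)
        ):
            s = 1.0 if xi > 0 else -1.0
            C = B + C - s * xi
            eta = eta - s * zeta
            xi = xi - 2.0 * s * B
            continue
        # step 6: |eta| <= A
        if gt(abs(eta), A) or (eq(eta, A) and lt(2 * xi, zeta)) or (
            eq(eta, -A) and lt(zeta, 0.0)
        ):
            s = 1.0 if eta > 0 else -1.0
            C = A + C - s * eta
            xi = xi - s * zeta
            eta = eta - 2.0 * s * A
            continue
        # step 7: |zeta| <= A
        if gt(abs(zeta), A) or (eq(zeta, A) and lt(2 * xi, eta)) or (
            eq(zeta, -A) and lt(eta, 0.0)
        ):
            s = 1.0 if zeta > 0 else -1.0
            B = A + B - s * zeta
            xi = xi - s * eta
            zeta = zeta - 2.0 * s * A
            continue
        # step 8: the body-diagonal condition
        total = xi + eta + zeta + A + B
        if lt(total, 0.0) or (eq(total, 0.0) and gt(2.0 * (A + eta) + zeta, 0.0)):
            C = A + B + C + xi + eta + zeta
            xi = 2.0 * B + xi + zeta
            eta = 2.0 * A + eta + zeta
            continue
        return _cell_from_niggli_params(A, B, C, xi, eta, zeta)
    raise ReductionError(
        f"Niggli reduction did not converge within {NIGGLI_MAX_STEPS} steps for {cell}"
    )


def reduce_to_p1(cell: UnitCell, sg: SpaceGroupInfo) -> P1Cell:
    """Canonical primitive P1 cell for a (cell, space group) pair."""
    reduced = niggli_reduce(primitive_cell(cell, sg))
    return P1Cell(cell=reduced, source_cell=cell, source_space_group=sg.canonical_symbol)
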