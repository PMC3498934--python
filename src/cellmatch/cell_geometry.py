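"""Unit-cell geometry: validation, Cartesian bases and superposition vertices.

A crystal unit cell is described by edge lengths a, b, c (in Å) and the
inter-axial angles alpha, beta, gamma (in degrees).  For superposition the
cell is realized as a Cartesian basis using the standard crystallographic
orthogonalization convention (a along x, b in the xy-plane, right-handed),
and represented by the four points O (origin) and A, B, C (the three axis
endpoints).  Every comparison downstream is between such four-point sets,
so the particular orthogonalization convention drops out after the optimal
rigid-body superposition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateCellError, SingularBasisError

#: Cells whose squared orthogonalization factor v^2 falls at or below this
#: are rejected as numerically degenerate (near-flat parallelepipeds).
V2_MIN = 1e-12


@dataclass(frozen=True)
class UnitCell:
    """Six cell parameters: lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    @property
    def lengths(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    @property
    def angles(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)

    def as_tuple(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    def __str__(self) -> str:  # "a,b,c,alpha,beta,gamma" round-trips via parse_cell
        return ",".join(f"{x:g}" for x in self.as_tuple())


@dataclass(frozen=True)
class CellVertices:
    """The four labelled superposition points of a cell: origin and axis tips."""

    O: np.ndarray
    A: np.ndarray
    B: np.ndarray
    C: np.ndarray

    def as_array(self) -> np.ndarray:
        """4x3 array in the fixed order O, A, B, C."""
        return np.stack([self.O, self.A, self.B, self.C])


def parse_cell(text: str) -> UnitCell:
    """Parse ``"a,b,c,alpha,beta,gamma"`` (six comma-separated numbers)."""
    parts = [p.strip() for p in text.split(",")]
    if len(parts) != 6:
        raise ValueError(
            f"expected 6 comma-separated cell parameters, got {len(parts)}: {text!r}"
        )
    try:
        vals = [float(p) for p in parts]
    except ValueError as exc:
        raise ValueError(f"non-numeric cell parameter in {text!r}: {exc}") from exc
    return validate_cell(UnitCell(*vals))


def orthogonalization_factor_sq(cell: UnitCell) -> float:
    """v^2 = 1 - cos^2(al) - cos^2(be) - cos^2(ga) + 2 cos(al) cos(be) cos(ga).

    v is the volume of the unit parallelepiped spanned by unit vectors with
    the cell's angles; v^2 > 0 iff the three angles are jointly realizable.
    """
    ca, cb, cg = (math.cos(math.radians(x)) for x in cell.angles)
    return 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg


def validate_cell(cell: UnitCell) -> UnitCell:
    """Return *cell* unchanged if geometrically realizable, else raise.

    Checks positive lengths, angles in the open interval (0°, 180°) and a
    strictly positive squared orthogonalization factor.
    """
    for name, value in zip("abc", cell.lengths):
        if not (value > 0.0 and math.isfinite(value)):
            raise DegenerateCellError(f"non-positive length {name} = {value}")
    for name, value in zip(("alpha", "beta", "gamma"), cell.angles):
        if not (0.0 < value < 180.0):
            raise DegenerateCellError(f"angle {name} = {value} outside (0, 180)")
    v2 = orthogonalization_factor_sq(cell)
    if v2 <= V2_MIN:
        raise DegenerateCellError(
            f"degenerate cell: squared orthogonalization factor v^2 = {v2:.3e} <= {V2_MIN}"
        )
    return cell


def cell_to_basis(cell: UnitCell) -> np.ndarray:
    """Cartesian basis (rows va, vb, vc) for a valid cell.

    Convention: va along +x, vb in the xy-plane with positive y component,
    vc completing a right-handed set (positive z component).
    """
    validate_cell(cell)
    a, b, c = cell.lengths
    alpha, beta, gamma = (math.radians(x) for x in cell.angles)
    ca, cb, cg = math.cos(alpha), math.cos(beta), math.cos(gamma)
    sg = math.sin(gamma)
    v = math.sqrt(orthogonalization_factor_sq(cell))
    return np.array(
        [
            [a, 0.0, 0.0],
            [b * cg, b * sg, 0.0],
            [c * cb, c * (ca - cb * cg) / sg, c * v / sg],
        ]
    )


def basis_to_cell(basis: np.ndarray) -> UnitCell:
    """Cell parameters (lengths + pairwise angles) of three basis row vectors.

    Lengths and angles are invariant under rotation and inversion, so any
    orientation (or handedness) of the same lattice basis gives the same cell.
    """
    basis = np.asarray(basis, dtype=float)
    if basis.shape != (3, 3):
        raise ValueError(f"expected a 3x3 basis, got shape {basis.shape}")
    if abs(np.linalg.det(basis)) < 1e-12:
        raise SingularBasisError("basis vectors are linearly dependent")
    norms = np.linalg.norm(basis, axis=1)
    va, vb, vc = basis

    def angle(u: np.ndarray, w: np.ndarray) -> float:
        cosang = float(np.dot(u, w) / (np.linalg.norm(u) * np.linalg.norm(w)))
        return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))

    return validate_cell(
        UnitCell(
            float(norms[0]), float(norms[1]), float(norms[2]),
            angle(vb, vc), angle(va, vc), angle(va, vb),
        )
    )


def cell_volume(cell: UnitCell) -> float:
    """Cell volume a·b·c·v in Å^3."""
    validate_cell(cell)
    a, b, c = cell.lengths
    return a * b * c * math.sqrt(orthogonalization_factor_sq(cell))


def cell_vertices(cell: UnitCell) -> CellVertices:
    """The four superposition points O=(0,0,0), A=va, B=vb, C=vc."""
    basis = cell_to_basis(cell)
    return CellVertices(np.zeros(3), basis[0], basis[1], basis[2])
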