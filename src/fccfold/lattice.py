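"""Face-centered-cubic lattice geometry.

The FCC lattice is modelled as the set of integer points ``(x, y, z)``
with even coordinate sum.  Every lattice point has 12 nearest neighbours,
reached by the 12 step vectors that have exactly two non-zero components,
each equal to +/-1.  Chain conformations use an *absolute* encoding: each
bond is one of the 12 directions, labelled 1..12.

The module also provides the 17 proper rotations of the FCC neighbour
shell that are used by rotation-based crossover: 9 "square-based"
rotations (90/180/270 degrees about the three coordinate axes) and 8
"triangle-hexagon-based" rotations (120/240 degrees about the four body
diagonals).  Each rotation acts on direction labels as a permutation of
1..12, so a rotated conformation is obtained by relabelling its bonds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

Point = Tuple[int, int, int]
Matrix = Tuple[Tuple[int, int, int], Tuple[int, int, int], Tuple[int, int, int]]

#: Direction labels 1..12 with their mnemonic and unit step vector.
#: Labels are paired with their opposites: 1/4, 2/3, 5/8, 6/7, 9/12, 10/11.
DIRECTIONS: dict[int, tuple[str, Point]] = {
    1: ("FL", (+1, +1, 0)),
    2: ("FR", (+1, -1, 0)),
    3: ("FU", (-1, +1, 0)),
    4: ("FD", (-1, -1, 0)),
    5: ("BL", (+1, 0, +1)),
    6: ("BR", (+1, 0, -1)),
    7: ("BU", (-1, 0, +1)),
    8: ("BD", (-1, 0, -1)),
    9: ("LU", (0, +1, +1)),
    10: ("LD", (0, +1, -1)),
    11: ("RU", (0, -1, +1)),
    12: ("RD", (0, -1, -1)),
}

#: The 12 step vectors in label order.
DIRECTION_VECTORS: tuple[Point, ...] = tuple(DIRECTIONS[l][1] for l in range(1, 13))

_VECTOR_TO_LABEL: dict[Point, int] = {v: l for l, (_, v) in DIRECTIONS.items()}

#: label -> opposite label (the direction with the negated vector).
OPPOSITE_LABEL: dict[int, int] = {
    l: _VECTOR_TO_LABEL[(-v[0], -v[1], -v[2])] for l, (_, v) in DIRECTIONS.items()
}


class InvalidLabelError(ValueError):
    """Raised for a direction label outside 1..12."""


class InvalidPointError(ValueError):
    """Raised for an integer triple with odd coordinate sum."""


def direction_vector(label: int) -> Point:
    """Return the unit step vector for a direction label (1..12)."""
    try:
        return DIRECTIONS[label][1]
    except (KeyError, TypeError):
        raise InvalidLabelError(f"direction label must be in 1..12, got {label!r}")


def vector_label(vector: Point) -> int:
    """Return the label of a step vector, or raise if it is not an FCC step."""
    try:
        return _VECTOR_TO_LABEL[tuple(vector)]
    except KeyError:
        raise InvalidLabelError(f"{vector!r} is not an FCC step vector")


def is_lattice_point(p: Sequence[int]) -> bool:
    return (p[0] + p[1] + p[2]) % 2 == 0


def neighbors(p: Point) -> set[Point]:
    """The 12 lattice points adjacent to ``p``."""
    if not is_lattice_point(p):
        raise InvalidPointError(f"{p!r} has odd coordinate sum")
    x, y, z = p
    return {(x + dx, y + dy, z + dz) for dx, dy, dz in DIRECTION_VECTORS}


def are_adjacent(p: Point, q: Point) -> bool:
    """True iff p and q are FCC nearest neighbours.

    Equivalent to: every componentwise absolute difference is <= 1 and the
    differences sum to 2 (i.e. the difference is one of the 12 step vectors).
    """
    dx = abs(p[0] - q[0])
    dy = abs(p[1] - q[1])
    dz = abs(p[2] - q[2])
    return dx <= 1 and dy <= 1 and dz <= 1 and dx + dy + dz == 2


def common_neighbors(p: Point, q: Point) -> set[Point]:
    """All lattice points adjacent to both p and q.

    For an adjacent pair the set always has exactly 4 elements; this is
    what gives the generalized pull move its per-step choice of 4 sites.
    """
    if p == q:
        raise ValueError("common_neighbors requires two distinct points")
    return neighbors(p) & neighbors(q)


# ---------------------------------------------------------------------------
# Rotations


@dataclass(frozen=True)
class LatticeRotation:
    """A proper rotation of the FCC neighbour shell.

    ``matrix`` is a 3x3 integer orthogonal matrix with determinant +1 that
    maps the 12 step vectors onto themselves; ``label_permutation`` is the
    induced bijection on labels, stored as a 13-tuple with entry 0 unused
    so that ``label_permutation[l]`` is the image of label ``l``.
    """

    id: str
    family: str  # "square" | "triangle-hexagon" | "identity"
    axis: Point
    angle: int  # degrees
    matrix: Matrix
    label_permutation: tuple[int, ...]

    def apply_point(self, p: Point) -> Point:
        m = self.matrix
        return (
            m[0][0] * p[0] + m[0][1] * p[1] + m[0][2] * p[2],
            m[1][0] * p[0] + m[1][1] * p[1] + m[1][2] * p[2],
            m[2][0] * p[0] + m[2][1] * p[1] + m[2][2] * p[2],
        )

    def apply_labels(self, labels: Iterable[int]) -> tuple[int, ...]:
        perm = self.label_permutation
        try:
            return tuple(perm[l] for l in labels)
        except (IndexError, TypeError):
            raise InvalidLabelError("labels must be integers in 1..12")


def _permutation_from_matrix(matrix: Matrix) -> tuple[int, ...]:
    perm = [0] * 13
    for l in range(1, 13):
        v = DIRECTIONS[l][1]
        image = (
            matrix[0][0] * v[0] + matrix[0][1] * v[1] + matrix[0][2] * v[2],
            matrix[1][0] * v[0] + matrix[1][1] * v[1] + matrix[1][2] * v[2],
            matrix[2][0] * v[0] + matrix[2][1] * v[1] + matrix[2][2] * v[2],
        )
        perm[l] = _VECTOR_TO_LABEL[image]
    return tuple(perm)


def _mat_mul(a: Matrix, b: Matrix) -> Matrix:
    return tuple(
        tuple(sum(a[i][k] * b[k][j] for k in range(3)) for j in range(3))
        for i in range(3)
    )  # type: ignore[return-value]


_IDENTITY_MATRIX: Matrix = ((1, 0, 0), (0, 1, 0), (0, 0, 1))

# 90-degree (counter-clockwise, right-hand rule) rotations about each axis.
_AXIS_QUARTER_TURNS: dict[str, tuple[Point, Matrix]] = {
    "x": ((1, 0, 0), ((1, 0, 0), (0, 0, -1), (0, 1, 0))),
    "y": ((0, 1, 0), ((0, 0, 1), (0, 1, 0), (-1, 0, 0))),
    "z": ((0, 0, 1), ((0, -1, 0), (1, 0, 0), (0, 0, 1))),
}

# 120-degree rotation about (1,1,1): cyclic coordinate shift x->y->z->x.
_DIAG_BASE: Matrix = ((0, 0, 1), (1, 0, 0), (0, 1, 0))

_BODY_DIAGONALS: tuple[Point, ...] = ((1, 1, 1), (1, 1, -1), (1, -1, 1), (-1, 1, 1))


def _make_rotation(id_: str, family: str, axis: Point, angle: int, matrix: Matrix) -> LatticeRotation:
    return LatticeRotation(
        id=id_,
        family=family,
        axis=axis,
        angle=angle,
        matrix=matrix,
        label_permutation=_permutation_from_matrix(matrix),
    )


def _build_rotations() -> tuple[LatticeRotation, ...]:
    rots: list[LatticeRotation] = []
    for name, (axis, quarter) in _AXIS_QUARTER_TURNS.items():
        m = _IDENTITY_MATRIX
        for angle in (90, 180, 270):
            m = _mat_mul(quarter, m)
            rots.append(_make_rotation(f"{name}{angle}", "square", axis, angle, m))
    for axis in _BODY_DIAGONALS:
        # Conjugate the (1,1,1) cyclic shift by the sign-flip diag(axis):
        # D @ M @ D fixes the requested diagonal and stays det +1.
        d: Matrix = (
            (axis[0], 0, 0),
            (0, axis[1], 0),
            (0, 0, axis[2]),
        )
        base = _mat_mul(d, _mat_mul(_DIAG_BASE, d))
        name = "d" + "".join("p" if c > 0 else "m" for c in axis)
        m = _IDENTITY_MATRIX
        for angle in (120, 240):
            m = _mat_mul(base, m)
            rots.append(_make_rotation(f"{name}{angle}", "triangle-hexagon", axis, angle, m))
    return tuple(rots)


#: The 17 non-identity rotations used by rotation-based crossover, in a
#: fixed deterministic order: x90, x180, x270, y90, ..., z270, then the
#: 120/240-degree body-diagonal rotations.
ROTATIONS: tuple[LatticeRotation, ...] = _build_rotations()

#: The identity, kept separate from the 17 and used by crossover as the
#: "no rotation" variant.
IDENTITY_ROTATION: LatticeRotation = _make_rotation(
    "identity", "identity", (0, 0, 0), 0, _IDENTITY_MATRIX
)


def enumerate_rotations() -> list[LatticeRotation]:
    """Return the 17 crossover rotations (stable order, identity excluded)."""
    return list(ROTATIONS)


def rotate_labels(rotation: LatticeRotation, labels: Iterable[int]) -> tuple[int, ...]:
    """Apply a rotation's label permutation elementwise."""
    return rotation.apply_labels(labels)


def rotations_table() -> list[dict]:
    """The 17 rotations as JSON-serialisable records (for docs/export)."""
    return [
        {
            "id": r.id,
            "family": r.family,
            "axis": list(r.axis),
            "angle": r.angle,
            "matrix": [list(row) for row in r.matrix],
            "permutation": {str(l): r.label_permutation[l] for l in range(1, 13)},
        }
        for r in ROTATIONS
    ]


def rotations_json(indent: int | None = 2) -> str:
    return json.dumps(rotations_table(), indent=indent)
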