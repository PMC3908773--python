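"""HP sequences, conformations and the contact energy.

A conformation of an ``n``-residue chain is an absolute direction-label
string of length ``n - 1``; residue 0 sits at the origin and residue ``i``
is obtained by adding the step vector of label ``i - 1``.  A conformation
is *valid* when the walk is self-avoiding.  The energy of a sequence on a
conformation is minus the number of HH contacts: pairs of H residues that
are non-consecutive in the chain (|i - j| > 1) but adjacent on the lattice.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterable, Sequence

from .lattice import (
    DIRECTION_VECTORS,
    InvalidLabelError,
    Point,
    direction_vector,
    vector_label,
)

HP_ALPHABET = frozenset("HP")


class InvalidSequenceError(ValueError):
    """Raised for a residue string containing characters other than H/P."""


class InvalidConformationError(ValueError):
    """Raised when an operation requires a self-avoiding conformation."""


class EncodingError(ValueError):
    """Raised when a coordinate trace cannot be encoded as FCC steps."""


def validate_hp_sequence(s: str) -> str:
    """Return ``s`` upper-cased, or raise if it is not a non-empty HP string."""
    s = s.strip().upper()
    if not s or not HP_ALPHABET.issuperset(s):
        bad = sorted(set(s) - HP_ALPHABET) if s else []
        raise InvalidSequenceError(
            f"HP sequence must be a non-empty string over {{H,P}}; got {bad or 'empty'}"
        )
    return s


def decode(labels: Sequence[int]) -> tuple[Point, ...]:
    """Coordinates of the walk encoded by ``labels``, anchored at the origin."""
    x = y = z = 0
    coords = [(0, 0, 0)]
    for l in labels:
        dx, dy, dz = direction_vector(l)
        x, y, z = x + dx, y + dy, z + dz
        coords.append((x, y, z))
    return tuple(coords)


def encode(coords: Sequence[Point]) -> tuple[int, ...]:
    """Direction labels of a coordinate trace (inverse of :func:`decode`)."""
    labels = []
    for a, b in zip(coords, coords[1:]):
        step = (b[0] - a[0], b[1] - a[1], b[2] - a[2])
        try:
            labels.append(vector_label(step))
        except InvalidLabelError:
            raise EncodingError(f"points {a} and {b} are not lattice-adjacent")
    return tuple(labels)


@dataclass(frozen=True)
class Conformation:
    """An absolute-direction chain embedding, anchored at the origin."""

    labels: tuple[int, ...]
    coords: tuple[Point, ...]

    @classmethod
    def from_labels(cls, labels: Iterable[int]) -> "Conformation":
        labels = tuple(labels)
        return cls(labels=labels, coords=decode(labels))

    @classmethod
    def from_coords(cls, coords: Sequence[Point]) -> "Conformation":
        labels = encode(coords)
        return cls(labels=labels, coords=decode(labels))

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def n(self) -> int:
        return len(self.coords)

    def is_valid(self) -> bool:
        return len(set(self.coords)) == len(self.coords)

    def occupancy(self) -> dict[Point, int]:
        """point -> residue index; requires a self-avoiding walk."""
        occ = {p: i for i, p in enumerate(self.coords)}
        if len(occ) != len(self.coords):
            raise InvalidConformationError("conformation is not self-avoiding")
        return occ

    def label_string(self) -> str:
        return ",".join(str(l) for l in self.labels)

    @classmethod
    def from_label_string(cls, text: str) -> "Conformation":
        parts = [p for p in text.replace(",", " ").split() if p]
        return cls.from_labels(int(p) for p in parts)


def is_valid_saw(c: Conformation) -> bool:
    """True iff all residue coordinates are pairwise distinct."""
    return c.is_valid()


def hh_contacts(s: str, c: Conformation) -> int:
    """Number of HH contacts of sequence ``s`` on conformation ``c``.

    A contact is a pair (i, j) with j >= i + 2, both residues H, and the
    two sites lattice-adjacent.
    """
    if len(s) != len(c.coords):
        raise ValueError(
            f"sequence length {len(s)} != conformation length {len(c.coords)}"
        )
    occ = c.occupancy()  # raises on a non-self-avoiding walk
    coords = c.coords
    count = 0
    for i, res in enumerate(s):
        if res != "H":
            continue
        x, y, z = coords[i]
        for dx, dy, dz in DIRECTION_VECTORS:
            j = occ.get((x + dx, y + dy, z + dz))
            if j is not None and j - i > 1 and s[j] == "H":
                count += 1
    return count


def contacts_for_indices(
    s: str, occ: dict[Point, int], coords: Sequence[Point], indices: Iterable[int]
) -> int:
    """HH contacts involving at least one residue in ``indices``.

    Helper for incremental move evaluation: pairs with both endpoints in
    ``indices`` are counted once.  ``occ`` must map every coordinate in
    ``coords`` to its residue index.
    """
    index_set = set(indices)
    doubled = 0
    for i in index_set:
        if s[i] != "H":
            continue
        x, y, z = coords[i]
        for dx, dy, dz in DIRECTION_VECTORS:
            j = occ.get((x + dx, y + dy, z + dz))
            if j is not None and abs(j - i) > 1 and s[j] == "H":
                doubled += 1 if j in index_set else 2
    return doubled // 2


@dataclass(frozen=True)
class EnergyValue:
    contacts: int

    @property
    def energy(self) -> int:
        return -self.contacts


def energy(s: str, c: Conformation) -> EnergyValue:
    """Free energy of ``s`` on ``c``: minus the HH-contact count."""
    return EnergyValue(contacts=hh_contacts(s, c))


def random_saw(n: int, rng: random.Random) -> Conformation:
    """A uniformly seeded random self-avoiding walk of ``n`` residues.

    Depth-first extension with a randomly shuffled direction order at every
    site, backtracking out of dead ends, so the walk always completes.  The
    distribution is not uniform over SAWs; it only needs to scatter the
    initial population.
    """
    if n < 1:
        raise ValueError("chain length must be >= 1")
    coords: list[Point] = [(0, 0, 0)]
    occupied: set[Point] = {(0, 0, 0)}
    # Stack of per-site untried direction lists.
    pending: list[list[Point]] = []
    vectors = list(DIRECTION_VECTORS)
    while len(coords) < n:
        if len(pending) < len(coords):
            options = vectors[:]
            rng.shuffle(options)
            pending.append(options)
        options = pending[-1]
        placed = False
        while options:
            dx, dy, dz = options.pop()
            x, y, z = coords[-1]
            nxt = (x + dx, y + dy, z + dz)
            if nxt not in occupied:
                coords.append(nxt)
                occupied.add(nxt)
                placed = True
                break
        if not placed:
            # Dead end: retract the last residue and keep trying above it.
            pending.pop()
            if len(coords) == 1:
                # Can only happen if n > available space; not reachable on FCC.
                raise RuntimeError("random walk generation exhausted the lattice")
            occupied.discard(coords.pop())
    return Conformation.from_coords(coords)
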