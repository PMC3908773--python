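"""Search operators: rotation-based crossover, generalized pull move, K-site move.

All operators preserve chain length and self-avoidance; any conformation
they return is valid.  Acceptance rules differ on purpose: the generalized
pull move is a strict hill-climber (it keeps a new conformation only when
the contact count strictly increases) while the K-site mutation also
accepts equal-energy rearrangements, which injects diversity.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional

from .conformation import Conformation, contacts_for_indices
from .lattice import (
    DIRECTION_VECTORS,
    IDENTITY_ROTATION,
    ROTATIONS,
    Point,
    are_adjacent,
)


class IncompatibleParentsError(ValueError):
    """Raised when crossover parents have different chain lengths."""


@dataclass
class CrossoverResult:
    offspring: list[Conformation]
    cut_point: int
    rotations_used: list[str]


@dataclass
class MoveOutcome:
    accepted: bool
    conformation: Conformation
    delta_contacts: int


@dataclass
class MoveStats:
    """Attempt/acceptance counters, for logging."""

    attempts: int = 0
    accepted: int = 0
    aborted: int = 0

    def rate(self) -> float:
        return self.accepted / self.attempts if self.attempts else 0.0


# ---------------------------------------------------------------------------
# Rotation-based crossover


def rotation_crossover(
    parent_a: Conformation,
    parent_b: Conformation,
    rng: random.Random,
    include_identity: bool = True,
    cut_point: Optional[int] = None,
) -> CrossoverResult:
    """One-point crossover with the swapped tail rotated through the lattice.

    The head (labels before the cut) comes from ``parent_a``; the tail
    (labels from the cut on) comes from ``parent_b`` and is emitted both
    unrotated and under each of the 17 FCC rotations, applied as label
    permutations.  Candidates that collide (non-self-avoiding) are dropped,
    so a call yields at most 18 valid offspring.  The classic second child
    is obtained by calling again with the parents swapped.
    """
    if parent_a.n != parent_b.n:
        raise IncompatibleParentsError(
            f"parent lengths differ: {parent_a.n} vs {parent_b.n}"
        )
    n = parent_a.n
    if n < 3:
        raise IncompatibleParentsError("crossover requires chains of length >= 3")
    if cut_point is None:
        cut_point = rng.randint(1, n - 2)
    elif not 1 <= cut_point <= n - 2:
        raise ValueError(f"cut point must be in 1..{n - 2}")

    head = parent_a.labels[:cut_point]
    tail = parent_b.labels[cut_point:]
    head_coords = parent_a.coords[: cut_point + 1]

    variants = ([IDENTITY_ROTATION] if include_identity else []) + list(ROTATIONS)
    offspring: list[Conformation] = []
    used: list[str] = []
    for rot in variants:
        perm = rot.label_permutation
        candidate_tail = tuple(perm[l] for l in tail)
        # Extend the fixed head, aborting early on any collision.
        occupied = set(head_coords)
        x, y, z = head_coords[-1]
        coords = list(head_coords)
        ok = True
        for l in candidate_tail:
            dx, dy, dz = DIRECTION_VECTORS[l - 1]
            x, y, z = x + dx, y + dy, z + dz
            p = (x, y, z)
            if p in occupied:
                ok = False
                break
            occupied.add(p)
            coords.append(p)
        if ok:
            offspring.append(
                Conformation(labels=head + candidate_tail, coords=tuple(coords))
            )
            used.append(rot.id)
    return CrossoverResult(offspring=offspring, cut_point=cut_point, rotations_used=used)


# ---------------------------------------------------------------------------
# Generalized pull move


def generalized_pull_move(
    s: str,
    c: Conformation,
    rng: random.Random,
    stats: Optional[MoveStats] = None,
) -> MoveOutcome:
    """One seeded generalized-pull-move attempt with strict-improvement acceptance.

    A start residue and a pull orientation (toward the head or the tail)
    are drawn uniformly.  The start residue is relocated to a random free
    neighbour of its predecessor along the pull orientation (for a chain
    end: of its single chain neighbour).  Connectivity is then restored by
    propagating along the chain: each next residue either is already
    adjacent to the previously moved one (done), or is pulled to a random
    free common neighbour of the moved residue's new site and its own
    current site — at most 4 candidates on the FCC lattice.  If a step has
    no free candidate the move aborts and the input is returned unchanged.
    The new conformation replaces the input only when its HH-contact count
    strictly exceeds the original's.
    """
    n = c.n
    if stats is not None:
        stats.attempts += 1
    if n < 2:
        return MoveOutcome(False, c, 0)

    coords = c.coords
    occ = c.occupancy()

    start = rng.randrange(n)
    toward_tail = rng.random() < 0.5
    step = 1 if toward_tail else -1
    prev_index = start - step  # predecessor along the pull orientation

    moved: dict[int, Point] = {}

    def free_neighbors(p: Point) -> list[Point]:
        out = []
        for dx, dy, dz in DIRECTION_VECTORS:
            q = (p[0] + dx, p[1] + dy, p[2] + dz)
            if q not in occ:
                out.append(q)
        return out

    # Initial relocation of the start residue.
    if 0 <= prev_index < n:
        anchor = coords[prev_index]
    else:
        # Terminal residue pulled outward: anchor on its single chain neighbour.
        anchor = coords[start + step]
    del occ[coords[start]]
    candidates = free_neighbors(anchor)
    if not candidates:
        if stats is not None:
            stats.aborted += 1
        return MoveOutcome(False, c, 0)
    new_pos = candidates[rng.randrange(len(candidates))]
    occ[new_pos] = start
    moved[start] = new_pos

    # Propagate along the chain until adjacency is restored.
    j = start + step
    prev_new = new_pos
    aborted = False
    while 0 <= j < n:
        cur = coords[j]
        if are_adjacent(prev_new, cur):
            break
        del occ[cur]
        options = [
            q
            for dx, dy, dz in DIRECTION_VECTORS
            if are_adjacent((q := (prev_new[0] + dx, prev_new[1] + dy, prev_new[2] + dz)), cur)
            and q not in occ
        ]
        if not options:
            aborted = True
            break
        new_pos = options[rng.randrange(len(options))]
        occ[new_pos] = j
        moved[j] = new_pos
        prev_new = new_pos
        j += step
    if aborted:
        if stats is not None:
            stats.aborted += 1
        return MoveOutcome(False, c, 0)

    # Delta evaluation over the moved residues only.
    old_occ = {p: i for i, p in enumerate(coords)}
    before = contacts_for_indices(s, old_occ, coords, moved)
    new_coords = list(coords)
    for i, p in moved.items():
        new_coords[i] = p
    after = contacts_for_indices(s, occ, new_coords, moved)
    delta = after - before
    if delta <= 0:
        return MoveOutcome(False, c, delta)

    new_conf = Conformation.from_coords(new_coords)
    if stats is not None:
        stats.accepted += 1
    return MoveOutcome(True, new_conf, delta)


# ---------------------------------------------------------------------------
# K-site move


def remaining_step_bound(p: Point, q: Point) -> int:
    """Admissible lower bound on the number of FCC steps from p to q.

    One step changes each coordinate by at most 1 (so at least the
    Chebyshev distance is needed) and the L1 norm by at most 2 (so at
    least ceil(L1/2) steps are needed).  The maximum of the two never
    exceeds the true FCC graph distance.
    """
    dx = abs(p[0] - q[0])
    dy = abs(p[1] - q[1])
    dz = abs(p[2] - q[2])
    return max(dx, dy, dz, (dx + dy + dz + 1) // 2)


def k_site_move(
    s: str,
    c: Conformation,
    K: int,
    rng: random.Random,
    stats: Optional[MoveStats] = None,
    prune: bool = True,
) -> MoveOutcome:
    """Re-route K consecutive residues between their flanking anchors.

    A start index is drawn uniformly; the K-segment's replacement paths —
    all self-avoiding chains of exactly K free sites connecting the two
    anchor residues (one anchor when the segment touches a chain end) —
    are enumerated depth-first, directions tried in label order.  With
    ``prune``, a partial path is cut as soon as its length plus the
    admissible remaining-step bound to the far anchor exceeds K + 1, which
    never discards a feasible path.  The candidate with the most HH
    contacts (first found on ties) replaces the segment when its contact
    count is at least the original's and the conformation changed.
    """
    n = c.n
    if not 1 <= K <= n:
        raise ValueError(f"K must be in 1..{n}, got {K}")
    if stats is not None:
        stats.attempts += 1

    start = rng.randrange(n - K + 1)
    segment = range(start, start + K)
    coords = c.coords
    occ = c.occupancy()
    for i in segment:
        del occ[coords[i]]

    left = coords[start - 1] if start > 0 else None
    right = coords[start + K] if start + K < n else None

    if left is None and right is None:
        # Whole-chain segment: regenerating from scratch is out of scope for
        # a local mutation; treat as a no-op.
        return MoveOutcome(False, c, 0)

    # Build from the anchored side; if only the right anchor exists, search
    # from it and reverse the found paths.
    reverse = left is None
    origin = right if reverse else left
    target = None if (left is None or right is None) else (left if reverse else right)

    best_path: Optional[list[Point]] = None
    best_contacts = -1
    orig_contacts: Optional[int] = None

    path: list[Point] = []

    def evaluate(candidate_path: list[Point]) -> int:
        ordered = list(reversed(candidate_path)) if reverse else candidate_path
        trial = list(coords)
        for idx, p in zip(segment, ordered):
            trial[idx] = p
        trial_occ = dict(occ)
        for idx, p in zip(segment, ordered):
            trial_occ[p] = idx
        return contacts_for_indices(s, trial_occ, trial, segment)

    def dfs(cur: Point, depth: int) -> None:
        nonlocal best_path, best_contacts
        if depth == K:
            if target is not None and not are_adjacent(cur, target):
                return
            score = evaluate(path)
            if score > best_contacts:
                best_contacts = score
                best_path = list(path)
            return
        for dx, dy, dz in DIRECTION_VECTORS:
            q = (cur[0] + dx, cur[1] + dy, cur[2] + dz)
            if q in occ or q in path:
                continue
            if (
                prune
                and target is not None
                and depth + 1 + remaining_step_bound(q, target) > K + 1
            ):
                continue
            path.append(q)
            dfs(q, depth + 1)
            path.pop()

    dfs(origin, 0)  # type: ignore[arg-type]

    if best_path is None:
        if stats is not None:
            stats.aborted += 1
        return MoveOutcome(False, c, 0)

    old_occ = {p: i for i, p in enumerate(coords)}
    orig_contacts = contacts_for_indices(s, old_occ, coords, segment)
    ordered = list(reversed(best_path)) if reverse else best_path
    if best_contacts < orig_contacts or ordered == [coords[i] for i in segment]:
        return MoveOutcome(False, c, 0)

    new_coords = list(coords)
    for idx, p in zip(segment, ordered):
        new_coords[idx] = p
    new_conf = Conformation.from_coords(new_coords)
    if stats is not None:
        stats.accepted += 1
    return MoveOutcome(True, new_conf, best_contacts - orig_contacts)
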