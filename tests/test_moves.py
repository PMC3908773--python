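"""Crossover, generalized pull move and K-site move operator contracts."""

import random
from collections import deque

import pytest

from fccfold.conformation import hh_contacts, random_saw
from fccfold.lattice import (
    DIRECTION_VECTORS,
    ROTATIONS,
    are_adjacent,
    common_neighbors,
    neighbors,
)
from fccfold.moves import (
    IncompatibleParentsError,
    MoveStats,
    generalized_pull_move,
    k_site_move,
    remaining_step_bound,
    rotation_crossover,
)


def random_hp(rng, n):
    return "".join(rng.choice("HP") for _ in range(n))


class TestRotationCrossover:
    def test_offspring_are_head_plus_permuted_tail(self):
        rng = random.Random(0)
        pa = random_saw(10, rng)
        pb = random_saw(10, rng)
        res = rotation_crossover(pa, pb, rng, cut_point=4)
        by_id = {r.id: r for r in ROTATIONS}
        for child, rot_id in zip(res.offspring, res.rotations_used):
            assert child.labels[:4] == pa.labels[:4]
            tail = pb.labels[4:]
            if rot_id == "identity":
                assert child.labels[4:] == tail
            else:
                assert child.labels[4:] == by_id[rot_id].apply_labels(tail)

    def test_self_cross_with_identity_recovers_parent(self):
        rng = random.Random(1)
        p = random_saw(8, rng)
        res = rotation_crossover(p, p, rng)
        assert res.rotations_used[0] == "identity"
        assert res.offspring[0].labels == p.labels

    def test_at_most_18_offspring_all_valid(self):
        rng = random.Random(2)
        for _ in range(200):
            n = rng.randint(3, 25)
            pa, pb = random_saw(n, rng), random_saw(n, rng)
            res = rotation_crossover(pa, pb, rng)
            assert 1 <= res.cut_point <= n - 2
            assert len(res.offspring) <= 18
            for child in res.offspring:
                assert len(child) == n
                assert child.is_valid()

    def test_identity_excludable(self):
        rng = random.Random(3)
        p = random_saw(8, rng)
        res = rotation_crossover(p, p, rng, include_identity=False)
        assert "identity" not in res.rotations_used
        assert len(res.offspring) <= 17

    def test_length_mismatch_rejected(self):
        rng = random.Random(4)
        with pytest.raises(IncompatibleParentsError):
            rotation_crossover(random_saw(5, rng), random_saw(6, rng), rng)

    def test_deterministic_under_seed(self):
        pa = random_saw(12, random.Random(5))
        pb = random_saw(12, random.Random(6))
        r1 = rotation_crossover(pa, pb, random.Random(9))
        r2 = rotation_crossover(pa, pb, random.Random(9))
        assert r1.cut_point == r2.cut_point
        assert [c.labels for c in r1.offspring] == [c.labels for c in r2.offspring]


class TestGeneralizedPullMove:
    def test_preserves_length_and_self_avoidance(self):
        rng = random.Random(10)
        for _ in range(500):
            n = rng.randint(2, 20)
            s = random_hp(rng, n)
            c = random_saw(n, rng)
            out = generalized_pull_move(s, c, rng)
            assert len(out.conformation) == n
            assert out.conformation.is_valid()

    def test_accepted_strictly_increases_contacts(self):
        rng = random.Random(11)
        accepted = 0
        for _ in range(800):
            n = rng.randint(6, 16)
            s = random_hp(rng, n)
            c = random_saw(n, rng)
            before = hh_contacts(s, c)
            out = generalized_pull_move(s, c, rng)
            after = hh_contacts(s, out.conformation)
            if out.accepted:
                accepted += 1
                assert after - before == out.delta_contacts
                assert out.delta_contacts >= 1
            else:
                assert out.conformation is c
        assert accepted > 0  # the operator does fire on random inputs

    def test_stats_counters(self):
        rng = random.Random(12)
        stats = MoveStats()
        for _ in range(200):
            c = random_saw(10, rng)
            generalized_pull_move("HPHHPPHHPH", c, rng, stats=stats)
        assert stats.attempts == 200
        assert 0 <= stats.accepted <= 200
        assert 0.0 <= stats.rate() <= 1.0


def _enumerate_gpm_proposals(c, forced_classic=False):
    """All coordinate tuples reachable by one pull-move propagation.

    Explores every start residue, orientation and per-step choice.  With
    ``forced_classic`` each pulled residue goes exactly to the site its
    predecessor vacated (the traditional pull move); the initial
    relocation is shared by both variants.
    """
    n = len(c.coords)
    results = set()
    for start in range(n):
        for step in (1, -1):
            prev_index = start - step
            anchor = c.coords[prev_index] if 0 <= prev_index < n else c.coords[start + step]
            base_occ = {p: i for i, p in enumerate(c.coords)}
            del base_occ[c.coords[start]]
            for first in neighbors(anchor):
                if first in base_occ:
                    continue

                def propagate(occ, moved, j, prev_new):
                    if not (0 <= j < n):
                        new_coords = list(c.coords)
                        for i, p in moved.items():
                            new_coords[i] = p
                        results.add(tuple(new_coords))
                        return
                    cur = c.coords[j]
                    if are_adjacent(prev_new, cur):
                        new_coords = list(c.coords)
                        for i, p in moved.items():
                            new_coords[i] = p
                        results.add(tuple(new_coords))
                        return
                    options = [
                        q
                        for q in common_neighbors(prev_new, cur)
                        if q not in occ or occ[q] == j
                    ]
                    if forced_classic:
                        prev_old = c.coords[j - step]
                        options = [q for q in options if q == prev_old]
                    for q in options:
                        occ2 = dict(occ)
                        del occ2[cur]
                        occ2[q] = j
                        propagate(occ2, {**moved, j: q}, j + step, q)

                occ = dict(base_occ)
                occ[first] = start
                propagate(occ, {start: first}, start + step, first)
    return results


class TestGpmMoveSet:
    def test_vacated_site_is_always_a_common_neighbor(self):
        # The site the predecessor vacated lies in the candidate set of the
        # next pulled residue, so classic pull results stay reachable.
        rng = random.Random(20)
        for _ in range(100):
            c = random_saw(8, rng)
            for j in range(1, 8):
                prev_old = c.coords[j - 1]
                # Wherever residue j-1 relocates (some neighbour of its old
                # site), its old site remains adjacent to both that new site
                # and residue j, hence among their <= 4 common neighbours.
                for new_prev in neighbors(prev_old):
                    if new_prev == c.coords[j]:
                        continue
                    assert prev_old in common_neighbors(new_prev, c.coords[j])

    def test_reachable_set_contains_classic_pull_results(self):
        rng = random.Random(21)
        for _ in range(15):
            n = rng.randint(4, 5)
            c = random_saw(n, rng)
            full = _enumerate_gpm_proposals(c)
            classic = _enumerate_gpm_proposals(c, forced_classic=True)
            assert classic <= full


class TestRemainingStepBound:
    def test_zero_iff_same_point(self):
        assert remaining_step_bound((0, 0, 0), (0, 0, 0)) == 0
        assert remaining_step_bound((0, 0, 0), (1, 1, 0)) == 1

    def test_admissible_against_bfs_distances(self):
        # BFS on the FCC graph from the origin, far enough to cover all
        # even-parity targets with |dx|,|dy|,|dz| <= 4.
        dist = {(0, 0, 0): 0}
        queue = deque([(0, 0, 0)])
        while queue:
            p = queue.popleft()
            if dist[p] >= 6:
                continue
            for dx, dy, dz in DIRECTION_VECTORS:
                q = (p[0] + dx, p[1] + dy, p[2] + dz)
                if q not in dist:
                    dist[q] = dist[p] + 1
                    queue.append(q)
        targets = [
            p for p in dist
            if max(abs(p[0]), abs(p[1]), abs(p[2])) <= 4
        ]
        assert len(targets) > 300
        for p in targets:
            assert remaining_step_bound((0, 0, 0), p) <= dist[p]


class TestKSiteMove:
    def test_preserves_length_sequence_and_validity(self):
        rng = random.Random(30)
        for _ in range(300):
            n = rng.randint(4, 16)
            s = random_hp(rng, n)
            c = random_saw(n, rng)
            out = k_site_move(s, c, 3, rng)
            assert len(out.conformation) == n
            assert out.conformation.is_valid()

    def test_accepted_never_decreases_contacts(self):
        rng = random.Random(31)
        for _ in range(300):
            n = rng.randint(5, 14)
            s = random_hp(rng, n)
            c = random_saw(n, rng)
            before = hh_contacts(s, c)
            out = k_site_move(s, c, 3, rng)
            after = hh_contacts(s, out.conformation)
            if out.accepted:
                assert after >= before
                assert out.conformation.coords != c.coords
            else:
                assert out.conformation is c

    def test_residues_outside_segment_unchanged(self):
        rng = random.Random(32)
        for _ in range(200):
            n = rng.randint(6, 14)
            s = random_hp(rng, n)
            c = random_saw(n, rng)
            out = k_site_move(s, c, 3, random.Random(rng.randrange(2**30)))
            if out.accepted:
                # Conformations are re-anchored at the origin, so compare the
                # bond labels: only the bonds touching one K=3 window change.
                diff = [
                    i
                    for i in range(n - 1)
                    if out.conformation.labels[i] != c.labels[i]
                ]
                assert diff
                assert max(diff) - min(diff) <= 3

    def test_pruned_matches_unpruned_exhaustive_search(self):
        rng = random.Random(33)
        for trial in range(80):
            n = rng.randint(5, 12)
            s = random_hp(rng, n)
            c = random_saw(n, rng)
            seed = rng.randrange(2**30)
            out_p = k_site_move(s, c, 3, random.Random(seed), prune=True)
            out_u = k_site_move(s, c, 3, random.Random(seed), prune=False)
            assert out_p.accepted == out_u.accepted
            assert out_p.conformation.coords == out_u.conformation.coords
            assert out_p.delta_contacts == out_u.delta_contacts

    def test_invalid_k_rejected(self):
        rng = random.Random(34)
        c = random_saw(5, rng)
        with pytest.raises(ValueError):
            k_site_move("HHHHH", c, 6, rng)
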