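# Methods

## Model

`fccfold` searches for minimum-energy conformations of hydrophobic-polar
(HP) protein chains on the 3D face-centered-cubic (FCC) lattice. The
lattice is the set of integer points (x, y, z) with x + y + z even; each
site has 12 nearest neighbours, reached by the step vectors with exactly
two non-zero components of ±1. A conformation of an n-residue chain is a
self-avoiding walk (SAW), stored as an absolute string of n − 1 direction
labels in 1..12 with residue 0 anchored at the origin. Conformations are
compared up to translation only; rotational duplicates may coexist in a
population.

The energy is E(c) = −(number of HH contacts), where an HH contact is a
pair of hydrophobic residues i, j with |i − j| > 1 occupying adjacent
lattice sites. Minimising E is maximising contacts; all user-facing
output reports the positive contact count.

Two printed-source ambiguities are resolved in the geometry layer:

* The direction table assigns the same vector to the labels BL and BR;
  label 6 (BR) is taken as (+1, 0, −1). This is the unique choice that
  keeps the 12 vectors pairwise distinct and closed under negation, and it
  keeps the z-axis quarter-turn label permutations consistent with the
  rest of the table (the test suite checks the permutation tuples
  exhaustively).
* The energy formula is stated without an explicit H-restriction; the
  contact predicate used here requires both residues to be H, per the
  model's definition of an HH contact.

## Search operators

**Rotation-based crossover.** One-point crossover on the label strings,
with the swapped tail additionally transformed by one of the 17 proper
rotations of the FCC neighbour shell: 9 square-based (90°/180°/270° about
the coordinate axes) and 8 triangle-hexagon-based (120°/240° about the
body diagonals). Because the encoding is absolute, a rotation acts on a
label substring as a fixed permutation of 1..12. One oriented call (head
from parent A, tail from parent B) emits the unrotated child plus the 17
rotated variants and keeps those that remain self-avoiding — at most 18
offspring; the EA calls the operator in both orientations. The six
remaining 180° edge rotations of the full octahedral group are
deliberately excluded, as are reflections.

**Generalized pull move (GPM).** A start residue and a pull orientation
are drawn uniformly. The start residue relocates to a uniformly chosen
free neighbour of its predecessor along the orientation (chain ends: of
their single neighbour). Connectivity is restored by propagation: the
next residue is either already adjacent to the moved one (stop) or is
pulled to a uniformly chosen free common neighbour of the moved residue's
new site and its own current site. An adjacent FCC site pair has exactly
4 common neighbours, and the vacated predecessor site is always among
them, so the classic pull move's outcome remains reachable. A step with
no free candidate aborts the move. Acceptance is strict improvement:
the new conformation replaces the input only if its contact count
increases. The move is evaluated incrementally (contacts involving moved
residues only), which keeps an attempt at O(moved × 12) hash lookups.

**K-site move.** Mutation re-routes K consecutive residues (default
K = 3) between their flanking anchor residues by depth-first enumeration
of all self-avoiding replacement paths of exactly K free sites, directions
tried in label order for reproducible tie-breaking. A partial path is
pruned when (steps taken) + bound(current, far anchor) > K + 1, where
bound(p, q) = max(Chebyshev(p − q), ⌈L1(p − q)/2⌉). One FCC step changes
each coordinate by at most 1 and the L1 norm by at most 2, so the bound
never exceeds the true lattice distance and pruning is exact: the pruned
search provably returns the same best candidate as un-pruned enumeration
(property-tested). A mixed step-count/Euclidean bound would be
unit-inconsistent on a lattice whose steps have length √2, which is why
the bound is formulated purely in steps. The best candidate replaces the
segment when its contact count is at least the original's — mutation may
move sideways, unlike GPM, to inject diversity.

## Evolutionary loop

Per generation: ⌊μ/2⌋ parent pairs are drawn by binary tournament
(fitter of two uniform draws, ties random); each pair undergoes
rotation-based crossover in both orientations with probability
`crossover_rate` (otherwise the parents are cloned); every offspring
receives `gpm_attempts_per_offspring` GPM attempts (default: the chain
length n, one expected pull opportunity per residue — measured on the
36-residue benchmark, doubling or tripling this budget does not change
the per-run success rate) and, with probability `mutation_rate`, one
K-site move; survivors are the top μ of parents ∪ offspring ((μ+λ)
truncation), so the best-so-far trajectory is monotone. Termination is a
fixed generation count. Defaults mirror the benchmark settings for short
chains: μ = 10, crossover 0.85, mutation 0.4, K = 3, 30 generations;
48-residue and longer benchmarks use μ = 40 and 150 generations.

Runs are exactly reproducible from (sequence, config, seed): a single
`random.Random(seed)` stream drives initialization and every operator.
`fold()` performs `restarts + 1` independent runs with seeds
seed, seed+1, … (mod 2³¹ − 1) and reports the best and the mean over
runs; when a reference contact count is supplied (`target_contacts`),
generation and restart loops stop as soon as it is reached — a known
optimum cannot be exceeded, so the reported maximum is unaffected.

Initial populations are random SAWs grown by depth-first extension with a
shuffled direction order and backtracking out of dead ends. The sampler
is not uniform over SAWs; it only needs to scatter the initial pool.

## Exhaustive oracle

For chains of up to 7 residues (cap raisable), `enumerate_optimum`
computes the exact optimum by depth-first enumeration of every SAW,
accumulating contacts incrementally as residues are placed. Since
contacts are invariant under the full 48-element cubic symmetry group,
the default mode fixes the first step to label 1 and restricts the first
non-collinear step to one representative per orbit of the stabilizer of
direction 1 ({2, 5, 7}, computed from the group at import time), a ~40×
reduction that provably preserves the optimum (tested against full
enumeration). With reduction enabled `walks_counted` is the number of
canonical walks enumerated; without it, the exact SAW count.

The oracle anchors the stochastic validation: over random sequences of
4–7 residues the EA at desk-scale settings must attain the enumerated
optimum in ≥ 95% of runs and can never exceed it.

## Benchmarks and HP encoding

Four benchmark sets ship as in-source fixtures, pinned by SHA-256 in the
test suite: eight classic sequences of 20–64 residues, ten 48-residue
sequences, fifteen long sequences (90–200 residues), and five real
protein sequences with their HP transforms. Known FCC optima
(established by exact constraint-programming methods) are stored as
`reference_optimum`, absent where no optimum has been established.

The amino-acid → HP map classifies {C, F, I, L, M, V, W, Y} as
hydrophobic. Tyrosine is included deliberately: it is the unique
single-residue assignment under which the computed transforms of all five
reference proteins match the reference HP strings character for
character (the round-trip is a test). The set is configurable.

## Problem sizes and limitations

The default test suite and the acceptance script validate the desk-scale
benchmarks: the 12-residue 1CNL sequence (optimum 7 contacts) and
S1–S4 (optima 23, 23, 17, 38), each with population 10, 30 generations
and up to 10 restarts — under a minute per sequence in pure Python.
Longer benchmarks use the same code path via the CLI
(`fccfold fold --benchmark H1`), with the 48-residue set configured at
population 40 and 150 generations; at those sizes a restart takes
minutes in pure Python, which is why they are exercised on demand rather
than in the default suite.

The per-run success rate on S4 is roughly 20%, so single runs are not a
reliable reproduction; the restart protocol is part of the method. At 48
residues and beyond, single restarts typically land a few contacts below
the known optima, and closing that gap requires restart budgets well
beyond the desk-scale settings used here.
Known limitations: the search is heuristic (no optimality certificate —
the oracle covers only short chains); the pairwise 20-amino-acid energy
functions, secondary-structure or disulfide constraints are extension
points, not implemented; twin removal and tabu/Monte-Carlo hybrids are
out of scope.
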