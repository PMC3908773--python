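# fccfold

Evolutionary search for protein folding on the 3D face-centered-cubic
(FCC) HP lattice model.

In the HP model a protein is a chain of hydrophobic (H) and polar (P)
residues embedded as a self-avoiding walk on a lattice; the free energy
is E(c) = −Σ contact(pᵢ, pⱼ), counting pairs of H residues that are
adjacent on the lattice but not consecutive in the chain (|i − j| > 1).
On the FCC lattice — integer points with even coordinate sum, 12
neighbours per site — this package searches for maximum-contact
conformations with an evolutionary algorithm built from three FCC-aware
operators:

* **rotation-based crossover** — one-point crossover where the exchanged
  tail is additionally transformed by one of the 17 proper rotations of
  the FCC neighbour shell (9 square-based about the coordinate axes, 8
  triangle-hexagon-based about the body diagonals), applied as
  permutations of the 12 direction labels; up to 18 candidate offspring
  per oriented parent pair, invalid ones filtered;
* **generalized pull move** — a pull move in which each pulled residue
  may occupy any free common neighbour (exactly 4 on FCC) of the
  previously moved residue's new site and its own site, accepted only on
  strict energy improvement;
* **K-site move** — exact re-routing of K consecutive residues (default
  K = 3) between their anchors by depth-first path enumeration with an
  admissible lower-bound pruning rule.

Selection is binary tournament; survival is elitist (μ+λ) truncation.
An exhaustive-enumeration oracle provides exact optima for short chains,
and the classic benchmark sequence sets (8 short sequences, ten
48-residue sequences, fifteen 90–200-residue sequences, and five real
proteins with HP transforms) ship as fixtures. See `docs/methods.md` for
the model and algorithm details.

Intended users: researchers and students working on lattice protein
structure prediction, heuristic conformational search, or benchmarking
of HP-model solvers.

## Worked example

Fold benchmark sequence S1 (20 residues, known FCC optimum 23 contacts):

```
$ fccfold fold --benchmark S1 --seed 0 --restarts 9
folding S1 (n=20) pop=10 iters=30 seed=0 restarts=9
run 0 (seed 0): best 22 contacts in 30 generations
run 1 (seed 1): best 23 contacts in 7 generations
{
  "name": "S1",
  "sequence": "HPHPPHHPHPPHPHHPPHPH",
  "best_contacts": 23,
  "best_energy": -23,
  "mean_contacts_over_restarts": 22.5,
  "best_labels": "1,12,11,4,10,8,8,9,7,5,6,9,6,8,10,4,2,1,11",
  ...
}
```

The first restart plateaus at 22 contacts; the second reaches the known
optimum of 23 (the run stops early because the benchmark's reference
optimum is reached, and an optimum cannot be exceeded). `best_labels` is
the conformation as absolute FCC direction labels (1–12); re-scoring it
reproduces the contact count:

```
$ fccfold energy --seq HPHPPHHPHPPHPHHPPHPH --labels 1,12,11,4,10,8,8,9,7,5,6,9,6,8,10,4,2,1,11
contacts	23
energy	-23
```

Other subcommands: `fccfold enumerate --seq HPHPH` (exact optimum for
short chains), `fccfold benchmarks` (list the packaged sequences),
`fccfold rotations` (the 17-rotation table as JSON). `fold` can also
write xyz CA traces (`--xyz`) and TSV coordinates (`--tsv`) for external
viewers.

Library use mirrors the CLI:

```python
from fccfold import EAConfig, fold
result = fold("HPHPPHHPHPPHPHHPPHPH", EAConfig(seed=0, restarts=9, target_contacts=23))
result.best_contacts        # 23
result.best.conformation    # label string + coordinates
```

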