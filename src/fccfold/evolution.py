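"""Evolutionary search driver.

One generation draws ``population_size / 2`` tournament-selected parent
pairs; each pair either undergoes rotation-based crossover in both
orientations (probability ``crossover_rate``), contributing every valid
rotated child, or is cloned.  Every offspring is then refined by repeated
generalized pull moves and, with probability ``mutation_rate``, perturbed
by a K-site move.  Survivor selection is elitist (mu + lambda) truncation
back to the population size, so the best-so-far trajectory never drops.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

from .conformation import Conformation, hh_contacts, random_saw, validate_hp_sequence
from .moves import MoveStats, generalized_pull_move, k_site_move, rotation_crossover

_SEED_MOD = 2**31 - 1


@dataclass(frozen=True)
class EAConfig:
    """Search hyperparameters.

    Defaults follow the benchmark settings for short chains: population 10,
    crossover rate 0.85, mutation rate 0.4, K = 3, 30 generations.
    ``gpm_attempts_per_offspring`` defaults (when None) to the chain
    length, giving each residue one expected pull opportunity per
    generation.  ``restarts`` counts additional independent runs beyond
    the first; ``target_contacts`` optionally stops a run (and the restart
    loop) as soon as a known reference contact count is reached.
    """

    population_size: int = 10
    crossover_rate: float = 0.85
    mutation_rate: float = 0.4
    iterations: int = 30
    K: int = 3
    tournament_size: int = 2
    gpm_attempts_per_offspring: Optional[int] = None
    seed: int = 0
    restarts: int = 0
    target_contacts: Optional[int] = None

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not (0.0 <= self.crossover_rate <= 1.0 and 0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("rates must lie in [0, 1]")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.K < 1:
            raise ValueError("K must be >= 1")


@dataclass
class Individual:
    conformation: Conformation
    contacts: int

    @classmethod
    def evaluated(cls, s: str, conformation: Conformation) -> "Individual":
        return cls(conformation=conformation, contacts=hh_contacts(s, conformation))


@dataclass
class RunResult:
    best: Individual
    best_per_generation: list[int]
    generations_run: int
    seed: int
    gpm_stats: MoveStats = field(default_factory=MoveStats)
    mutation_stats: MoveStats = field(default_factory=MoveStats)


@dataclass
class FoldResult:
    """Aggregate over independent restarts."""

    best: Individual
    runs: list[RunResult]

    @property
    def best_contacts(self) -> int:
        return self.best.contacts

    @property
    def mean_contacts(self) -> float:
        return sum(r.best.contacts for r in self.runs) / len(self.runs)


def initialize_population(
    s: str, cfg: EAConfig, rng: random.Random
) -> list[Individual]:
    """Random self-avoiding walks, evaluated and sorted by contacts (desc)."""
    n = len(s)
    pop = [Individual.evaluated(s, random_saw(n, rng)) for _ in range(cfg.population_size)]
    pop.sort(key=lambda ind: ind.contacts, reverse=True)
    return pop


def tournament_select(population: list[Individual], rng: random.Random) -> Individual:
    """Binary tournament: the fitter of two uniform draws (ties random)."""
    if not population:
        raise ValueError("population is empty")
    a = population[rng.randrange(len(population))]
    b = population[rng.randrange(len(population))]
    if a.contacts != b.contacts:
        return a if a.contacts > b.contacts else b
    return a if rng.random() < 0.5 else b


def survivor_selection(
    parents: list[Individual], offspring: list[Individual], cfg: EAConfig
) -> list[Individual]:
    """(mu + lambda) truncation: top ``population_size`` of the joint pool."""
    pool = parents + offspring
    if not pool:
        raise ValueError("survivor pool is empty")
    pool.sort(key=lambda ind: ind.contacts, reverse=True)
    return pool[: cfg.population_size]


def run_ea(s: str, cfg: EAConfig, seed: Optional[int] = None) -> RunResult:
    """One seeded EA run; fully reproducible from (sequence, config, seed)."""
    s = validate_hp_sequence(s)
    if len(s) < 3:
        raise ValueError("the EA requires chains of length >= 3")
    if seed is None:
        seed = cfg.seed
    rng = random.Random(seed)
    gpm_attempts = (
        cfg.gpm_attempts_per_offspring
        if cfg.gpm_attempts_per_offspring is not None
        else len(s)
    )
    gpm_stats = MoveStats()
    mut_stats = MoveStats()

    population = initialize_population(s, cfg, rng)
    best = population[0]
    best_per_generation: list[int] = []
    generations = 0

    for _ in range(cfg.iterations):
        generations += 1
        offspring: list[Individual] = []
        for _ in range(cfg.population_size // 2):
            pa = tournament_select(population, rng)
            pb = tournament_select(population, rng)
            if rng.random() < cfg.crossover_rate:
                children: list[Conformation] = []
                children.extend(
                    rotation_crossover(pa.conformation, pb.conformation, rng).offspring
                )
                children.extend(
                    rotation_crossover(pb.conformation, pa.conformation, rng).offspring
                )
            else:
                children = [pa.conformation, pb.conformation]
            for child in children:
                for _ in range(gpm_attempts):
                    outcome = generalized_pull_move(s, child, rng, stats=gpm_stats)
                    child = outcome.conformation
                if rng.random() < cfg.mutation_rate:
                    child = k_site_move(s, child, cfg.K, rng, stats=mut_stats).conformation
                offspring.append(Individual.evaluated(s, child))
        population = survivor_selection(population, offspring, cfg)
        if population[0].contacts > best.contacts:
            best = population[0]
        best_per_generation.append(best.contacts)
        if cfg.target_contacts is not None and best.contacts >= cfg.target_contacts:
            break

    return RunResult(
        best=best,
        best_per_generation=best_per_generation,
        generations_run=generations,
        seed=seed,
        gpm_stats=gpm_stats,
        mutation_stats=mut_stats,
    )


def fold(s: str, cfg: EAConfig) -> FoldResult:
    """Run the EA over ``cfg.restarts + 1`` independent seeded runs.

    Restart ``i`` uses seed ``(cfg.seed + i) mod (2^31 - 1)``.  When
    ``cfg.target_contacts`` is set, the restart loop stops as soon as one
    run reaches it (later restarts cannot improve on a known optimum).
    """
    runs: list[RunResult] = []
    best: Optional[Individual] = None
    for i in range(cfg.restarts + 1):
        result = run_ea(s, cfg, seed=(cfg.seed + i) % _SEED_MOD)
        runs.append(result)
        if best is None or result.best.contacts > best.contacts:
            best = result.best
        if cfg.target_contacts is not None and best.contacts >= cfg.target_contacts:
            break
    assert best is not None
    return FoldResult(best=best, runs=runs)
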