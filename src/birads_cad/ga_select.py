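"""Modified genetic feature selection over integer feature-id chromosomes.

Unlike classic bit-mask GA selection, a chromosome is a fixed-length
sequence of L distinct feature ids from 1..F, so every individual encodes
a subset of exactly L features.  Reproduction combines elitism (the best
two chromosomes survive unchanged), roulette-wheel parent selection,
(L-1)-point crossover (genes alternate between the parents positionally)
and a duplicate-repairing mutation that replaces repeated ids with fresh
random ones, plus a low-rate (P_m = 0.01) random resetting.  The search is
run once per subset size L; the sweep over all L yields per-size bests and
a global optimum.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

FitnessFn = Callable[[tuple[int, ...]], float]


@dataclass
class Chromosome:
    """A candidate feature subset: L distinct ids with cached fitness."""

    genes: tuple[int, ...]
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.genes = tuple(int(g) for g in self.genes)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("chromosome genes must be distinct")

    @property
    def subset(self) -> frozenset[int]:
        return frozenset(self.genes)


@dataclass
class GAConfig:
    L: int
    population_base: int = 5          # population size = 4 * population_base
    elitism_count: int = 2
    crossover_prob: float = 1.0
    mutation_prob: float = 0.01
    stagnation_x: int = 10
    max_generations: int = 60
    n_features: int = 130
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 4 or self.population_size % 4 != 0:
            raise ValueError("population size must be >= 4 and divisible by 4")
        if self.elitism_count != 2:
            raise ValueError("elitism count is fixed to 2")

    @property
    def population_size(self) -> int:
        return 4 * self.population_base


@dataclass
class GARun:
    """Result of one GA run: the best-ever chromosome and its trajectory."""

    best: Chromosome
    history: list[float]
    evaluations: int


@dataclass
class SweepResult:
    """Best subset per explored chromosome length and the global optimum."""

    per_L: dict[int, Chromosome]
    global_best: Chromosome
    global_L: int

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "per_L": {
                str(L): {"ids": sorted(ch.genes), "fitness": ch.fitness}
                for L, ch in sorted(self.per_L.items())
            },
            "global_best": {
                "L": self.global_L,
                "ids": sorted(self.global_best.genes),
                "fitness": self.global_best.fitness,
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def init_population(cfg: GAConfig, rng: np.random.Generator | None = None) -> list[Chromosome]:
    """Uniform random L-subsets of 1..F, deterministically seeded."""
    if cfg.L > cfg.n_features:
        raise ValueError(f"L={cfg.L} exceeds the feature count {cfg.n_features}")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    return [
        Chromosome(tuple(rng.choice(cfg.n_features, size=cfg.L, replace=False) + 1))
        for _ in range(cfg.population_size)
    ]


def roulette_probabilities(fitnesses: Sequence[float]) -> np.ndarray:
    """Selection probabilities proportional to fitness: P(ci)=f(ci)/sum f."""
    f = np.asarray(fitnesses, dtype=float)
    if f.size == 0:
        raise ValueError("no fitnesses")
    if (f < 0).any():
        raise ValueError("fitnesses must be non-negative")
    total = f.sum()
    if total == 0:
        logger.warning("all-zero fitness: uniform selection probabilities")
        return np.full(f.size, 1.0 / f.size)
    return f / total


def kpoint_crossover(
    p1: Chromosome | Sequence[int],
    p2: Chromosome | Sequence[int],
    rng: np.random.Generator | None = None,
) -> tuple[list[int], list[int]]:
    """(L-1)-point crossover: genes alternate between the parents.

    With a crossover point between every adjacent gene pair, child 1 takes
    parent 1's genes at even positions (0-based) and parent 2's at odd
    positions; child 2 takes the converse.  Children may contain duplicate
    ids; the mutation operator repairs them.
    """
    g1 = list(getattr(p1, "genes", p1))
    g2 = list(getattr(p2, "genes", p2))
    if len(g1) != len(g2):
        raise ValueError("parents must have equal length")
    if len(g1) < 2:
        raise ValueError("crossover requires L >= 2")
    c1 = [g1[i] if i % 2 == 0 else g2[i] for i in range(len(g1))]
    c2 = [g2[i] if i % 2 == 0 else g1[i] for i in range(len(g1))]
    return c1, c2


def mutate(
    genes: Sequence[int],
    cfg: GAConfig,
    rng: np.random.Generator,
) -> Chromosome:
    """Repair duplicated ids, then apply low-probability random resetting.

    Every repetition of an id beyond its first occurrence is replaced by a
    uniformly random id not currently in the chromosome (guided mutation);
    independently, each gene is reset with probability P_m to a random
    absent id.
    """
    out = [int(g) for g in genes]
    if any(not 1 <= g <= cfg.n_features for g in out):
        raise ValueError("gene ids must lie in 1..F")
    seen: set[int] = set()
    for idx, g in enumerate(out):
        if g in seen:
            pool = np.array(sorted(set(range(1, cfg.n_features + 1)) - set(out) - seen))
            out[idx] = int(rng.choice(pool))
        seen.add(out[idx])
    for idx in range(len(out)):
        if rng.random() < cfg.mutation_prob:
            pool = np.array(sorted(set(range(1, cfg.n_features + 1)) - set(out)))
            if pool.size:
                out[idx] = int(rng.choice(pool))
    return Chromosome(tuple(out))


class _CachedFitness:
    """Order-insensitive memoization so each subset is scored once per run."""

    def __init__(self, fn: FitnessFn):
        self.fn = fn
        self.cache: dict[frozenset[int], float] = {}
        self.evaluations = 0

    def __call__(self, genes: tuple[int, ...]) -> float:
        key = frozenset(genes)
        if key not in self.cache:
            value = float(self.fn(tuple(sorted(key))))
            if value < 0:
                raise ValueError("fitness must be non-negative")
            self.cache[key] = value
            self.evaluations += 1
        return self.cache[key]


def run_ga(L: int, fitness_fn: FitnessFn, cfg: GAConfig) -> GARun:
    """Generational GA for one subset size L.

    Each generation the two elites are copied unchanged and the rest of
    the population is rebuilt from roulette-selected parents via crossover
    (P_c = 1) and mutation.  The loop stops after ``stagnation_x``
    generations without improvement of the best fitness, or at
    ``max_generations``; the best-ever chromosome is returned.
    """
    cfg = replace(cfg, L=L)
    rng = np.random.default_rng(cfg.seed)
    fitness = _CachedFitness(fitness_fn)
    population = init_population(cfg, rng)
    best: Chromosome | None = None
    history: list[float] = []
    stagnation = 0
    for _ in range(cfg.max_generations):
        scores = np.array([fitness(ch.genes) for ch in population])
        for ch, s in zip(population, scores):
            ch.fitness = float(s)
        gen_best = population[int(np.argmax(scores))]
        if best is None or gen_best.fitness > best.fitness:
            best = Chromosome(gen_best.genes, gen_best.fitness)
            stagnation = 0
        else:
            stagnation += 1
        history.append(best.fitness)
        # elitism guarantees the running best never decreases
        assert len(history) < 2 or history[-1] >= history[-2]
        if stagnation >= cfg.stagnation_x:
            break
        order = np.argsort(scores)[::-1]
        elites = [Chromosome(population[i].genes, float(scores[i])) for i in order[:2]]
        # best-ever re-seeded alongside the generation elites
        if best.subset not in {e.subset for e in elites}:
            elites[1] = Chromosome(best.genes, best.fitness)
        probs = roulette_probabilities(scores)
        children: list[Chromosome] = list(elites)
        while len(children) < cfg.population_size:
            i, j = rng.choice(len(population), size=2, p=probs)
            # a chromosome encodes an unordered subset, so each parent's
            # gene order is re-randomized before the positional exchange;
            # otherwise ids compete for fixed slots and two genes stuck at
            # the same position can never be combined into one child
            g1 = tuple(rng.permutation(population[int(i)].genes))
            g2 = tuple(rng.permutation(population[int(j)].genes))
            if cfg.L >= 2 and rng.random() < cfg.crossover_prob:
                c1, c2 = kpoint_crossover(g1, g2, rng)
            else:
                c1, c2 = list(g1), list(g2)
            children.append(mutate(c1, cfg, rng))
            if len(children) < cfg.population_size:
                children.append(mutate(c2, cfg, rng))
        population = children
    best = Chromosome(best.genes, fitness(best.genes))
    return GARun(best=best, history=history, evaluations=fitness.evaluations)


def default_schedule(F: int, L: int, seed: int = 0) -> GAConfig:
    """Population/generation schedule that shrinks slowly as L grows."""
    population_base = max(5, int(np.ceil((F - L + 4) / 4)))
    max_generations = max(15, 60 - L // 3)
    return GAConfig(
        L=L,
        population_base=population_base,
        max_generations=max_generations,
        n_features=F,
        seed=seed,
    )


def exhaustive_best(L: int, fitness_fn: FitnessFn, F: int) -> Chromosome:
    """Brute-force enumeration of all C(F, L) subsets (small F only)."""
    best_genes, best_fit = None, -1.0
    for genes in combinations(range(1, F + 1), L):
        f = float(fitness_fn(genes))
        if f > best_fit:
            best_genes, best_fit = genes, f
    return Chromosome(best_genes, best_fit)


def sweep(
    fitness_fn: FitnessFn,
    F: int = 130,
    cfg_schedule: Callable[[int], GAConfig] | None = None,
    lmin: int = 1,
    lmax: int | None = None,
    seed: int = 0,
) -> SweepResult:
    """Search the best feature subset of every size L in [lmin, lmax].

    L = 1 is solved exhaustively (every single feature is scored), L = F
    by scoring the full set once; intermediate sizes run the GA with a
    per-L configuration from ``cfg_schedule`` (default:
    ``default_schedule``).  The global best is the fittest per-L winner,
    ties breaking toward fewer features.
    """
    if F < 2:
        raise ValueError("need at least 2 features to sweep")
    lmax = F if lmax is None else lmax
    if not 1 <= lmin <= lmax <= F:
        raise ValueError("require 1 <= lmin <= lmax <= F")
    if cfg_schedule is None:
        cfg_schedule = lambda L: default_schedule(F, L, seed=seed + L)
    per_L: dict[int, Chromosome] = {}
    for L in range(lmin, lmax + 1):
        if L == 1:
            scores = [(float(fitness_fn((fid,))), fid) for fid in range(1, F + 1)]
            best_f, best_id = max(scores)
            per_L[L] = Chromosome((best_id,), best_f)
        elif L == F:
            full = tuple(range(1, F + 1))
            per_L[L] = Chromosome(full, float(fitness_fn(full)))
        else:
            per_L[L] = run_ga(L, fitness_fn, cfg_schedule(L)).best
        logger.info("sweep L=%d best fitness=%.4f", L, per_L[L].fitness)
    global_L = min(per_L, key=lambda L: (-per_L[L].fitness, L))
    return SweepResult(per_L=per_L, global_best=per_L[global_L], global_L=global_L)
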