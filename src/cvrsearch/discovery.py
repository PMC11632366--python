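"""Genetic-algorithm search over ratio genomes, plus a brute-force oracle.

The search encodes a candidate biomarker as an integer vector over searchable
units (0 = numerator, 1 = excluded, 2 = denominator) and evolves a population
of 32 by tournament selection (3 picks, with replacement), blend crossover,
and stagnation-adaptive mutation, with single-copy elitism and constraint
repair after every variation step.  Fitness evaluations are memoized by
genome key, since small populations revisit genomes constantly.

Blend crossover on the integer alphabet is realized as BLX-alpha with
clamp-and-round: per gene, a value is drawn uniformly on the interval
spanned by the parents extended by alpha times their gap, clamped to [0, 2]
and rounded to the nearest integer.  Uniform crossover is available behind a
config switch.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .composites import CompositeConfig, RatioSpec, SearchSpace
from .data_io import RegionalDataset, RegionMetadata
from .trial_power import CandidateEvaluator, EvaluationResult, TrialDesign

__all__ = [
    "GAConfig",
    "SearchResult",
    "initialize_population",
    "tournament_select",
    "blend_crossover",
    "adaptive_mutate",
    "run_search",
    "brute_force_search",
]


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings (defaults: population 32, 300 generations,
    tournament of 3, blend crossover alpha 0.5, per-gene base mutation rate
    1/L boosted on stagnation, one elite)."""

    population_size: int = 32
    generations: int = 300
    tournament_size: int = 3
    blend_alpha: float = 0.5
    base_mutation_rate: float | None = None  # None -> 1/genome_length
    stagnation_window: int = 10
    mutation_boost: float = 2.0
    max_mutation_rate: float = 0.5
    elitism_count: int = 1
    seed: int = 0
    crossover: str = "blend"  # or "uniform"
    sse_exponent: float = 2.0
    top_n: int = 5
    frozen_assignments: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.tournament_size < 1 or self.tournament_size > self.population_size:
            raise ValueError("tournament_size must be in [1, population_size]")
        if self.base_mutation_rate is not None and not 0 <= self.base_mutation_rate <= 1:
            raise ValueError("base_mutation_rate must be in [0, 1]")
        if not 0 <= self.max_mutation_rate <= 1:
            raise ValueError("max_mutation_rate must be in [0, 1]")
        if self.crossover not in ("blend", "uniform"):
            raise ValueError(f"unknown crossover: {self.crossover!r}")
        if self.elitism_count < 0 or self.elitism_count >= self.population_size:
            raise ValueError("elitism_count must be in [0, population_size)")


@dataclass(frozen=True)
class SearchResult:
    """Outcome of one GA run."""

    best_genome: tuple[int, ...]
    best_spec: RatioSpec
    best_result: EvaluationResult
    trace_best: np.ndarray   # best-so-far fitness, length generations+1
    trace_mean: np.ndarray   # per-generation mean of finite fitnesses
    top: tuple[tuple[tuple[int, ...], EvaluationResult], ...]
    n_evaluations: int
    cache_hits: int
    space_units: tuple[str, ...]
    config: GAConfig

    @property
    def best_fitness(self) -> float:
        return self.best_result.fitness

    def to_dict(self) -> dict:
        return {
            "best_genome": list(self.best_genome),
            "units": list(self.space_units),
            "best": self.best_result.to_dict(),
            "best_fitness": None if not math.isfinite(self.best_fitness) else self.best_fitness,
            "trace_best": [None if not math.isfinite(v) else v for v in self.trace_best],
            "trace_mean": [None if not math.isfinite(v) else v for v in self.trace_mean],
            "top": [
                {"genome": list(g), **r.to_dict()} for g, r in self.top
            ],
            "n_evaluations": self.n_evaluations,
            "cache_hits": self.cache_hits,
        }


def initialize_population(
    config: GAConfig, space: SearchSpace, rng: np.random.Generator
) -> list[np.ndarray]:
    """Uniform random genomes, repaired; pinned genes applied by repair."""
    return [space.random_genome(rng) for _ in range(config.population_size)]


def tournament_select(
    population: Sequence[np.ndarray],
    fitnesses: Sequence[float],
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw k members uniformly with replacement; return the fittest
    (ties go to the first drawn)."""
    idx = rng.integers(0, len(population), size=k)
    best = idx[int(np.argmax([fitnesses[i] for i in idx]))]
    return population[int(best)]


def blend_crossover(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    space: SearchSpace,
    alpha: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """BLX-alpha on the {0,1,2} alphabet with clamp + round-half-up, then repair."""
    a = np.asarray(parent_a, dtype=float)
    b = np.asarray(parent_b, dtype=float)
    gap = np.abs(a - b)
    lo = np.minimum(a, b) - alpha * gap
    hi = np.maximum(a, b) + alpha * gap
    u = rng.uniform(lo, hi)
    child = np.clip(np.floor(u + 0.5), 0, 2).astype(np.int8)
    return space.repair(child, rng)


def uniform_crossover(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    space: SearchSpace,
    rng: np.random.Generator,
) -> np.ndarray:
    pick = rng.random(len(parent_a)) < 0.5
    child = np.where(pick, parent_a, parent_b).astype(np.int8)
    return space.repair(child, rng)


def adaptive_mutate(
    genome: np.ndarray,
    space: SearchSpace,
    rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Resample each unpinned gene to one of the two other alleles with
    probability ``rate``, then repair."""
    if not 0 <= rate <= 1:
        raise ValueError("mutation rate must be in [0, 1]")
    g = np.asarray(genome, dtype=np.int8).copy()
    mask = (rng.random(len(g)) < rate) & ~space.frozen_mask
    if mask.any():
        shift = rng.integers(1, 3, size=int(mask.sum()))
        g[mask] = (g[mask] + shift) % 3
    return space.repair(g, rng)


def run_search(
    dataset: RegionalDataset,
    meta: RegionMetadata,
    composite_config: CompositeConfig,
    design: TrialDesign,
    ga_config: GAConfig | None = None,
) -> SearchResult:
    """Elitist generational GA over the constrained genome space.

    Candidate-level failures (non-convergent fits, degenerate ratios) are
    absorbed as invalid-fitness sentinels; only an infeasible constraint
    configuration raises.
    """
    cfg = ga_config or GAConfig()
    rng = np.random.default_rng(cfg.seed)
    space = SearchSpace.from_metadata(
        meta, composite_config.laterality, frozen_assignments=cfg.frozen_assignments
    )
    evaluator = CandidateEvaluator(
        dataset, meta, composite_config, design, sse_exponent=cfg.sse_exponent
    )
    L = len(space)
    base_rate = cfg.base_mutation_rate if cfg.base_mutation_rate is not None else 1.0 / L
    rate = base_rate

    population = initialize_population(cfg, space, rng)
    results = [evaluator.evaluate_genome(g, space) for g in population]
    fits = [r.fitness for r in results]

    best_idx = int(np.argmax(fits))
    best_genome = population[best_idx].copy()
    best_fit = fits[best_idx]
    trace_best = [best_fit]
    trace_mean = [_finite_mean(fits)]
    stagnation = 0

    for _ in range(cfg.generations):
        order = np.argsort(fits)[::-1]
        new_pop = [population[int(i)].copy() for i in order[: cfg.elitism_count]]
        while len(new_pop) < cfg.population_size:
            pa = tournament_select(population, fits, cfg.tournament_size, rng)
            pb = tournament_select(population, fits, cfg.tournament_size, rng)
            if cfg.crossover == "blend":
                child = blend_crossover(pa, pb, space, cfg.blend_alpha, rng)
            else:
                child = uniform_crossover(pa, pb, space, rng)
            child = adaptive_mutate(child, space, rate, rng)
            new_pop.append(child)
        population = new_pop
        results = [evaluator.evaluate_genome(g, space) for g in population]
        fits = [r.fitness for r in results]
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = fits[gen_best]
            best_genome = population[gen_best].copy()
            stagnation = 0
            rate = base_rate
        else:
            stagnation += 1
            if stagnation % cfg.stagnation_window == 0:
                rate = min(rate * cfg.mutation_boost, cfg.max_mutation_rate)
        trace_best.append(best_fit)
        trace_mean.append(_finite_mean(fits))

    ranked = sorted(
        evaluator.cache.items(), key=lambda kv: kv[1].fitness, reverse=True
    )[: cfg.top_n]
    best_result = evaluator.cache[tuple(int(v) for v in best_genome)]
    return SearchResult(
        best_genome=tuple(int(v) for v in best_genome),
        best_spec=best_result.spec,
        best_result=best_result,
        trace_best=np.asarray(trace_best),
        trace_mean=np.asarray(trace_mean),
        top=tuple((k, v) for k, v in ranked),
        n_evaluations=evaluator.n_evaluations,
        cache_hits=evaluator.cache_hits,
        space_units=space.units,
        config=cfg,
    )


def _finite_mean(fits: Sequence[float]) -> float:
    finite = [f for f in fits if math.isfinite(f)]
    return float(np.mean(finite)) if finite else -math.inf


def brute_force_search(
    dataset: RegionalDataset,
    meta: RegionMetadata,
    composite_config: CompositeConfig,
    design: TrialDesign,
    max_units: int = 8,
    sse_exponent: float = 2.0,
    frozen_assignments: Mapping[str, int] | None = None,
) -> tuple[tuple[int, ...], EvaluationResult, int]:
    """Exhaustively evaluate every constraint-valid genome (test oracle).

    Returns (best genome, its evaluation, number of genomes enumerated).
    Refuses problems with more than ``max_units`` searchable units.
    """
    space = SearchSpace.from_metadata(
        meta, composite_config.laterality, frozen_assignments=frozen_assignments
    )
    if len(space) > max_units:
        raise ValueError(
            f"{len(space)} units exceeds max_units={max_units}: brute force refused"
        )
    evaluator = CandidateEvaluator(
        dataset, meta, composite_config, design, sse_exponent=sse_exponent
    )
    allowed = []
    for i in range(len(space)):
        if i in space.frozen:
            allowed.append((space.frozen[i],))
        else:
            vals = [1]
            if space.numerator_ok[i]:
                vals.append(0)
            if space.denominator_ok[i]:
                vals.append(2)
            allowed.append(tuple(sorted(vals)))
    best: tuple[tuple[int, ...], EvaluationResult] | None = None
    count = 0
    for combo in itertools.product(*allowed):
        g = np.asarray(combo, dtype=np.int8)
        if not (g == 0).any() or not (g == 2).any():
            continue
        count += 1
        res = evaluator.evaluate_genome(g, space)
        if best is None or res.fitness > best[1].fitness:
            best = (combo, res)
    if best is None:
        raise ValueError("no constraint-valid genome exists")
    return best[0], best[1], count
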