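"""Genetic-algorithm stage of the neural-genetic classifier.

Individuals are real-coded vectors of L normalized sensor features (one
gene per sensor channel, values in [0, 1]).  The per-gene fitness is

    f(x) = x + K * |sin(32 x)|,   0 <= x < pi,

with K the preprocessing window size; a chromosome's fitness is the mean
per-gene value, which keeps the formula intact while making fitness
independent of chromosome length.  Since genes live in [0, 1] the domain
constraint 0 <= x < pi is automatic; angles are radians, so the factor 32
puts about ten ripples of the sine across the unit interval.

Evolution is the canonical generational loop — fitness-proportionate
(roulette-wheel) selection, one-point crossover, per-gene uniform-reset
mutation — with an elitist preserving strategy: the strongest individuals
are copied unchanged into the next generation, so the best fitness never
decreases.  The loop stops as soon as the best fitness reaches the
configured threshold (default 0.5) or the generation budget is spent.

Used inside the classification pipeline, the GA acts as a stochastic
refinement of observed feature vectors: the population is seeded with
jittered copies of the measurements and the surviving elite is the
denoised feature vector handed to the neural stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_DOMAIN_HIGH = np.pi


@dataclass
class GAConfig:
    """Knobs of the genetic stage.

    Defaults follow the standard operating point of this classifier:
    population 1,500, at most 200 generations, crossover probability
    0.18, mutation probability 0.01, fitness threshold 0.5, single-elite
    preservation.
    """

    population_size: int = 1500
    max_generations: int = 200
    crossover_prob: float = 0.18
    mutation_prob: float = 0.01
    fitness_threshold: float = 0.5
    window: int = 10
    elite_count: int = 1
    chromosome_length: int = 8
    seed_fraction: float = 1.0
    jitter: float = 0.01

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for name in ("crossover_prob", "mutation_prob", "seed_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.fitness_threshold < 0:
            raise ValueError("fitness_threshold must be >= 0")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not 0 <= self.elite_count < self.population_size:
            raise ValueError("elite_count must be in [0, population_size)")
        if self.chromosome_length < 1:
            raise ValueError("chromosome_length must be >= 1")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")


def fitness(x, window: int):
    """Per-gene fitness f(x) = x + K * |sin(32 x)| on [0, pi)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0) or np.any(arr >= _DOMAIN_HIGH):
        raise ValueError("fitness argument must lie in [0, pi)")
    out = arr + window * np.abs(np.sin(32.0 * arr))
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def chromosome_fitness(genes, window: int) -> float:
    """Mean per-gene fitness of one chromosome."""
    genes = np.asarray(genes, dtype=float)
    return float(np.mean(fitness(genes, window)))


def population_fitness(genes: np.ndarray, window: int) -> np.ndarray:
    """Vectorized chromosome fitness for a (n, L) gene matrix."""
    genes = np.asarray(genes, dtype=float)
    if np.any(genes < 0) or np.any(genes >= _DOMAIN_HIGH):
        raise ValueError("genes must lie in [0, pi)")
    return np.mean(genes + window * np.abs(np.sin(32.0 * genes)), axis=1)


@dataclass
class Population:
    """Gene matrix (n, L) with per-individual fitness."""

    genes: np.ndarray
    fitness: np.ndarray

    def __post_init__(self):
        self.genes = np.asarray(self.genes, dtype=float)
        self.fitness = np.asarray(self.fitness, dtype=float)
        if self.genes.ndim != 2 or self.fitness.shape != (self.genes.shape[0],):
            raise ValueError("genes must be (n, L) with one fitness per row")

    @property
    def size(self) -> int:
        return self.genes.shape[0]

    @property
    def best_index(self) -> int:
        return int(np.argmax(self.fitness))

    @property
    def best(self) -> np.ndarray:
        return self.genes[self.best_index]

    @property
    def best_fitness(self) -> float:
        return float(self.fitness[self.best_index])


def init_population(features, config: GAConfig,
                    rng: np.random.Generator | int | None = None) -> Population:
    """Build the initial population from observed feature vectors.

    A fraction ``seed_fraction`` of individuals are copies of observed
    vectors (drawn with replacement) perturbed by Gaussian jitter and
    clipped back into [0, 1]; the remainder are uniform on [0, 1]^L.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    feats = np.atleast_2d(np.asarray(features, dtype=float)) if features is not None else None
    n, L = config.population_size, config.chromosome_length
    n_seeded = int(round(config.seed_fraction * n))
    if n_seeded > 0:
        if feats is None or feats.size == 0:
            raise ValueError("seeding requested but no feature vectors supplied")
        if feats.shape[1] != L:
            raise ValueError("feature vectors must match the chromosome length")
        if np.any(feats < 0) or np.any(feats > 1):
            raise ValueError("features must be normalized into [0, 1]")
    genes = rng.random((n, L))
    if n_seeded > 0:
        picks = rng.integers(0, feats.shape[0], size=n_seeded)
        seeded = feats[picks]
        if config.jitter > 0:
            seeded = seeded + rng.normal(0.0, config.jitter, size=seeded.shape)
        genes[:n_seeded] = np.clip(seeded, 0.0, 1.0)
    return Population(genes=genes, fitness=population_fitness(genes, config.window))


def select(population: Population, rng: np.random.Generator) -> tuple[int, int]:
    """Roulette-wheel selection of a parent pair (indices, with replacement).

    Selection probability is proportional to fitness; when the total
    fitness mass is zero the wheel degenerates to a uniform draw.
    """
    if population.size < 2:
        raise ValueError("need at least 2 individuals to select parents")
    total = population.fitness.sum()
    if total > 0:
        p = population.fitness / total
        i, j = rng.choice(population.size, size=2, p=p)
    else:
        i, j = rng.integers(0, population.size, size=2)
    return int(i), int(j)


def crossover(a, b, rng: np.random.Generator):
    """One-point crossover at a uniform random cut in {1, ..., L-1}.

    The two offspring jointly carry exactly the parents' genes at every
    locus (the per-locus multiset is preserved).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("parents must have equal length")
    L = a.size
    if L < 2:
        return a.copy(), b.copy()
    cut = int(rng.integers(1, L))
    child1 = np.concatenate([a[:cut], b[cut:]])
    child2 = np.concatenate([b[:cut], a[cut:]])
    return child1, child2


def mutate(genes, mutation_prob: float, rng: np.random.Generator) -> np.ndarray:
    """Independently reset each gene to uniform [0, 1] with probability pm."""
    if not 0.0 <= mutation_prob <= 1.0:
        raise ValueError("mutation probability must lie in [0, 1]")
    genes = np.asarray(genes, dtype=float).copy()
    mask = rng.random(genes.size) < mutation_prob
    genes[mask] = rng.random(int(mask.sum()))
    return genes


@dataclass
class EvolutionResult:
    population: Population
    history: list = field(default_factory=list)  # (generation, best, mean)
    generations: int = 0
    converged: bool = False

    @property
    def elite(self) -> np.ndarray:
        return self.population.best

    @property
    def best_fitness(self) -> float:
        return self.population.best_fitness


def evolve(population: Population, config: GAConfig,
           rng: np.random.Generator | int | None = None) -> EvolutionResult:
    """Elitist generational loop until the fitness threshold is reached.

    Each generation copies the ``elite_count`` fittest individuals
    unchanged, then fills the population with offspring of roulette-
    selected parents, crossed over with probability ``crossover_prob``
    (cloned otherwise) and mutated gene-wise.  Stops as soon as the best
    fitness is >= ``fitness_threshold``, or after ``max_generations``.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    pop = population
    history = [(0, pop.best_fitness, float(pop.fitness.mean()))]
    gen = 0
    while pop.best_fitness < config.fitness_threshold and gen < config.max_generations:
        gen += 1
        order = np.argsort(pop.fitness)[::-1]
        children = [pop.genes[i].copy() for i in order[: config.elite_count]]
        while len(children) < config.population_size:
            i, j = select(pop, rng)
            a, b = pop.genes[i], pop.genes[j]
            if rng.random() < config.crossover_prob:
                a, b = crossover(a, b, rng)
            else:
                a, b = a.copy(), b.copy()
            children.append(mutate(a, config.mutation_prob, rng))
            if len(children) < config.population_size:
                children.append(mutate(b, config.mutation_prob, rng))
        genes = np.vstack(children)
        pop = Population(genes=genes, fitness=population_fitness(genes, config.window))
        history.append((gen, pop.best_fitness, float(pop.fitness.mean())))
    return EvolutionResult(population=pop, history=history, generations=gen,
                           converged=pop.best_fitness >= config.fitness_threshold)


def denoise(features, config: GAConfig,
            rng: np.random.Generator | int | None = None) -> EvolutionResult:
    """Seed a population from observed features, evolve, return the result.

    The elite individual of the final population is the GA-denoised
    feature vector passed on to the neural stage.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    pop = init_population(features, config, rng)
    return evolve(pop, config, rng)
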