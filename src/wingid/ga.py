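"""Small real-coded genetic algorithm used for RBF-SVM hyperparameter search.

Tournament selection, arithmetic crossover, Gaussian mutation, elitism.
Fully deterministic given the caller's `numpy` Generator.  Fitness values are
memoized per genome so elites are never re-evaluated.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ga_maximize"]


def ga_maximize(
    fitness,
    bounds,
    rng: np.random.Generator,
    population: int = 20,
    generations: int = 30,
    crossover_rate: float = 0.8,
    mutation_rate: float = 0.1,
    tournament_k: int = 3,
    elitism: int = 1,
    include=(),
):
    """Maximize ``fitness(genome)`` over a box.

    Parameters
    ----------
    bounds : sequence of (lo, hi)
        Search box, one pair per gene.
    include : sequence of genomes
        Genomes injected into the initial population (e.g. a known-good
        default); with elitism the result can never score below the best of
        these on the same fitness.

    Returns
    -------
    (best_genome, best_fitness, history)
        ``history`` is the best fitness per generation (non-decreasing).
    """
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    dim = len(bounds)
    if population < 2:
        raise ValueError("population must be >= 2")

    pop = rng.uniform(lo, hi, size=(population, dim))
    for i, g in enumerate(include):
        if i >= population:
            break
        pop[i] = np.clip(np.asarray(g, dtype=float), lo, hi)

    cache: dict = {}

    def evaluate(genome: np.ndarray) -> float:
        key = tuple(np.round(genome, 12))
        if key not in cache:
            cache[key] = float(fitness(genome))
        return cache[key]

    fit = np.array([evaluate(g) for g in pop])
    history = [fit.max()]

    def tournament() -> np.ndarray:
        idx = rng.integers(0, population, size=tournament_k)
        return pop[idx[np.argmax(fit[idx])]]

    mut_sd = 0.1 * (hi - lo)
    for _ in range(generations):
        order = np.argsort(fit)[::-1]
        new = [pop[i].copy() for i in order[:elitism]]
        while len(new) < population:
            p1, p2 = tournament(), tournament()
            if rng.random() < crossover_rate:
                u = rng.random(dim)
                child = u * p1 + (1.0 - u) * p2
            else:
                child = p1.copy()
            mut = rng.random(dim) < mutation_rate
            child = child + mut * rng.normal(0.0, mut_sd, size=dim)
            new.append(np.clip(child, lo, hi))
        pop = np.asarray(new)
        fit = np.array([evaluate(g) for g in pop])
        history.append(fit.max())

    best = int(np.argmax(fit))
    return pop[best].copy(), float(fit[best]), np.asarray(history)
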