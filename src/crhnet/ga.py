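"""Genetic-algorithm wrapper feature selection over 5-gene chromosomes.

A chromosome is an unordered subset of k distinct genes from the preselected
pool, scored by the LOOCV classification accuracy of the MLHD/LDA classifier
on the time-point factor (its *fitness*).  Each search evolves a population
by fitness-proportional selection, single-point crossover on the sorted gene
representation and per-slot mutation, and stops as soon as any chromosome
reaches the goal fitness (100% LOOCV accuracy by default) or the generation
budget runs out.  The search is restarted up to ``max_solutions`` times to
collect many distinct solutions, genes are ranked by how often they occur in
goal-reaching chromosomes, and a consensus over independent repetitions
keeps the genes present in at least ``min_runs`` of the top-N lists.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import RatioMatrix
from .discriminant import loocv_predictions

logger = logging.getLogger(__name__)


@dataclass
class GaParams:
    """Search parameters for one GA repetition."""

    k: int = 5
    goal_fitness: float = 1.0
    max_solutions: int = 2500
    max_generations: int = 200
    population_size: int = 50
    crossover_rate: float = 1.0
    mutation_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("chromosome size k must be >= 2")
        if not (0 < self.crossover_rate <= 1 and 0 < self.mutation_rate <= 1):
            raise ValueError("rates must be in (0, 1]")


@dataclass
class SelectionRun:
    """One selector run: solutions, frequency ranking, and error estimate."""

    method: str
    params: object
    solutions: list                    # tuples of gene ids at goal fitness
    ranking: pd.DataFrame              # index gene id, columns freq, rank
    n_attempts: int
    seed: int
    error: float | None = None         # method-specific error estimate
    extras: dict = field(default_factory=dict)

    def top(self, n: int = 50) -> list:
        """Gene ids of the top-n ranking rows (full list if shorter)."""
        if n > len(self.ranking):
            warnings.warn(
                f"top={n} exceeds ranking length {len(self.ranking)}; "
                "using the full list",
                stacklevel=2,
            )
        return list(self.ranking.index[:n])


class FitnessCache:
    """Memoized LOOCV fitness over chromosomes of one pool.

    ``X`` is (samples x genes); chromosomes are sorted tuples of column
    indices.  ``evaluations`` counts actual classifier LOOCV passes (cache
    hits are free), which the annealer uses for its budget bookkeeping.
    """

    def __init__(self, X: np.ndarray, labels: np.ndarray):
        from .discriminant import _loocv_core

        self.X = np.asarray(X, dtype=float)
        self.labels = np.asarray(labels)
        _classes, self._y_idx = np.unique(self.labels, return_inverse=True)
        self._counts = np.bincount(self._y_idx)
        n = self.X.shape[0]
        self._onehot = np.zeros((self._counts.size, n))
        self._onehot[self._y_idx, np.arange(n)] = 1.0
        self._core = _loocv_core
        self._cache: dict = {}
        self.evaluations = 0

    def __call__(self, chrom: tuple) -> float:
        hit = self._cache.get(chrom)
        if hit is not None:
            return hit
        pred = self._core(
            self.X[:, list(chrom)], self._y_idx, self._counts, self._onehot
        )
        acc = float(np.mean(pred == self._y_idx))
        self._cache[chrom] = acc
        self.evaluations += 1
        return acc


def _pool_arrays(pool: RatioMatrix) -> tuple[np.ndarray, np.ndarray]:
    return pool.matrix().T, pool.time


def random_chromosome(
    n_genes: int, k: int, rng: np.random.Generator
) -> tuple:
    return tuple(sorted(rng.choice(n_genes, size=k, replace=False)))


def _repair(child: list, n_genes: int, rng: np.random.Generator) -> tuple:
    """Replace duplicate gene slots with fresh random pool genes."""
    seen: set = set()
    out = []
    for g in child:
        while g in seen:
            g = int(rng.integers(n_genes))
        seen.add(g)
        out.append(g)
    return tuple(sorted(out))


def _mutate(
    chrom: tuple, n_genes: int, rate: float, rng: np.random.Generator
) -> tuple:
    genes = list(chrom)
    for slot in range(len(genes)):
        if rng.random() < rate:
            g = int(rng.integers(n_genes))
            while g in genes:
                g = int(rng.integers(n_genes))
            genes[slot] = g
    return tuple(sorted(genes))


def evolve_one_solution(
    fitness: FitnessCache,
    n_genes: int,
    params: GaParams,
    rng: np.random.Generator,
) -> tuple | None:
    """Run one GA until a chromosome reaches the goal fitness.

    Returns the winning chromosome (sorted gene-index tuple), or None when
    the generation budget is exhausted without reaching the goal.
    """
    if n_genes < params.k:
        raise ValueError("pool smaller than chromosome size")
    if n_genes < params.k + 1:
        raise ValueError("pool leaves no room for mutation")
    pop = [
        random_chromosome(n_genes, params.k, rng)
        for _ in range(params.population_size)
    ]
    fits = np.array([fitness(c) for c in pop])
    best = int(np.argmax(fits))
    if fits[best] >= params.goal_fitness:
        return pop[best]

    for _gen in range(params.max_generations):
        # fitness-proportional selection on min-shifted fitness, so the
        # worst chromosome has (almost) no reproduction probability
        shifted = fits - fits.min() + 1e-6
        probs = shifted / shifted.sum()
        elite = pop[int(np.argmax(fits))]
        children = [elite]
        while len(children) < params.population_size:
            i, j = rng.choice(len(pop), size=2, p=probs)
            p1, p2 = pop[i], pop[j]
            if rng.random() < params.crossover_rate:
                cut = int(rng.integers(1, params.k))
                c1 = _repair(list(p1[:cut] + p2[cut:]), n_genes, rng)
                c2 = _repair(list(p2[:cut] + p1[cut:]), n_genes, rng)
            else:
                c1, c2 = p1, p2
            children.append(_mutate(c1, n_genes, params.mutation_rate, rng))
            if len(children) < params.population_size:
                children.append(
                    _mutate(c2, n_genes, params.mutation_rate, rng)
                )
        pop = children
        fits = np.array([fitness(c) for c in pop])
        best = int(np.argmax(fits))
        if fits[best] >= params.goal_fitness:
            return pop[best]
    return None


def rank_by_frequency(solutions, gene_ids=None) -> pd.DataFrame:
    """Frequency ranking of genes over goal-reaching chromosomes.

    Counts, per gene, the number of solution chromosomes containing it and
    sorts by (frequency descending, gene id ascending) — the deterministic
    tie-break.  ``solutions`` may hold tuples of gene ids directly, or of
    integer indices resolved through ``gene_ids``.
    """
    counts: dict = {}
    for chrom in solutions:
        for g in chrom:
            gid = gene_ids[g] if gene_ids is not None else g
            counts[gid] = counts.get(gid, 0) + 1
    if not counts:
        return pd.DataFrame(columns=["frequency", "rank"])
    table = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["gene", "frequency"],
    ).set_index("gene")
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def run_ga(pool: RatioMatrix, params: GaParams) -> SelectionRun:
    """Collect up to ``max_solutions`` goal-fitness chromosomes by restarts.

    Every stored solution is re-scored with an independent LOOCV pass before
    ranking (no stale caches).  Duplicate solutions are counted as separate
    occurrences; the number of unique chromosomes is reported in
    ``extras['n_unique']``.
    """
    X, labels = _pool_arrays(pool)
    fitness = FitnessCache(X, labels)
    rng = np.random.default_rng(params.seed)
    gene_ids = pool.gene_ids
    solutions = []
    for _ in range(params.max_solutions):
        win = evolve_one_solution(fitness, len(gene_ids), params, rng)
        if win is None:
            continue
        recheck = loocv_predictions(X[:, list(win)], labels)
        if float(np.mean(recheck == labels)) >= params.goal_fitness:
            solutions.append(win)
    if not solutions:
        warnings.warn("GA collected no goal-fitness chromosomes", stacklevel=2)
    ranking = rank_by_frequency(solutions, gene_ids)
    logger.info(
        "GA: %d/%d attempts reached goal fitness (%d unique chromosomes, "
        "%d fitness evaluations)",
        len(solutions), params.max_solutions,
        len(set(solutions)), fitness.evaluations,
    )
    return SelectionRun(
        method="ga_mlhd",
        params=params,
        solutions=[tuple(gene_ids[g] for g in c) for c in solutions],
        ranking=ranking,
        n_attempts=params.max_solutions,
        seed=params.seed,
        extras={
            "n_unique": len(set(solutions)),
            "fitness_evaluations": fitness.evaluations,
        },
    )


def repeated_runs(
    pool: RatioMatrix, params: GaParams, n_runs: int = 4
) -> list[SelectionRun]:
    """Independent GA repetitions with per-run seeds spawned from the master."""
    seeds = np.random.SeedSequence(params.seed).generate_state(n_runs)
    runs = []
    for s in seeds:
        p = GaParams(**{**params.__dict__, "seed": int(s % 2**31)})
        runs.append(run_ga(pool, p))
    return runs


def pooled_ranking(runs) -> pd.DataFrame:
    """Frequency ranking over the solutions of several repetitions pooled.

    Used for cross-method top-list comparisons: pooling the repetitions
    stabilizes the low-frequency tail of the ranking.
    """
    return rank_by_frequency([c for run in runs for c in run.solutions])


def consensus(runs, top: int = 50, min_runs: int = 3) -> list:
    """Genes present in the top-``top`` list of at least ``min_runs`` runs."""
    if len(runs) < min_runs:
        raise ValueError("fewer runs supplied than min_runs")
    counts: dict = {}
    for run in runs:
        for g in run.top(top):
            counts[g] = counts.get(g, 0) + 1
    return sorted(g for g, c in counts.items() if c >= min_runs)
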