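"""Simulated-annealing gene-subset selection (the INSEL procedure).

The search space and energy are the same as for the genetic algorithm: a
state is a k-gene chromosome and its energy is the LOOCV classification
*error* of the MLHD/LDA classifier.  A move mutates one uniformly chosen
slot to a gene not currently in the chromosome, and is accepted by the
Metropolis rule at the scheduled temperature.  The starting temperature is
calibrated from the data: the mean absolute successive difference of the
energies of many randomly drawn chromosomes (the mean variation of the
generalized energy).  The cooling schedule follows the classical SANN
variant: T_t = T0 / ln(floor((t-1)/tmax) * tmax + e), i.e. the temperature
is lowered every ``tmax`` evaluations.

As with the GA, many annealing restarts are collected, chromosomes reaching
perfect LOOCV accuracy are kept, and genes are ranked by occurrence
frequency in those solutions.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .containers import RatioMatrix
from .discriminant import loocv_predictions
from .ga import FitnessCache, SelectionRun, random_chromosome, rank_by_frequency

logger = logging.getLogger(__name__)

#: Floor for a degenerate (zero) calibrated starting temperature.
T0_FLOOR = 1e-3


@dataclass
class SaParams:
    """Annealer parameters for one repetition."""

    k: int = 5
    maxit: int = 1000
    n_calibration: int = 10000
    max_solutions: int = 2500
    goal_accuracy: float = 1.0
    tmax: int = 10                 # evaluations per temperature level
    temp_method: str = "mean_abs_diff"   # or "std"
    seed: int = 0

    def __post_init__(self):
        if self.maxit < 1:
            raise ValueError("maxit must be >= 1")
        if self.n_calibration < 2:
            raise ValueError("n_calibration must be >= 2")
        if self.temp_method not in ("mean_abs_diff", "std"):
            raise ValueError("temp_method must be 'mean_abs_diff' or 'std'")


def estimate_initial_temperature(
    fitness: FitnessCache,
    n_genes: int,
    params: SaParams,
    rng: np.random.Generator,
) -> float:
    """Data-calibrated starting temperature.

    Draws ``n_calibration`` random chromosomes, computes each one's LOOCV
    classification error (the generalized energy), and returns the mean
    absolute difference between successive energies in that stream (or the
    standard deviation of the energies with ``temp_method='std'``).  A
    degenerate all-equal energy landscape gets the small floor ``T0_FLOOR``.
    """
    energies = np.array([
        1.0 - fitness(random_chromosome(n_genes, params.k, rng))
        for _ in range(params.n_calibration)
    ])
    if params.temp_method == "std":
        t0 = float(np.std(energies))
    else:
        t0 = float(np.mean(np.abs(np.diff(energies))))
    if t0 <= 0:
        warnings.warn(
            "constant energy landscape during calibration; "
            f"starting temperature floored at {T0_FLOOR}",
            stacklevel=2,
        )
        t0 = T0_FLOOR
    return t0


def metropolis_accept(
    delta_e: float, temperature: float, rng: np.random.Generator
) -> bool:
    """Metropolis rule: accept with probability min(1, exp(-dE/T))."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta_e <= 0:
        return True
    return rng.random() < math.exp(-delta_e / temperature)


def _temperature(t0: float, step: int, tmax: int) -> float:
    """SANN logarithmic cooling, lowered every ``tmax`` evaluations."""
    return t0 / math.log(((step - 1) // tmax) * tmax + math.e)


def _neighbor(
    chrom: tuple, n_genes: int, rng: np.random.Generator
) -> tuple:
    """Mutate one uniformly chosen slot to a pool gene outside the chromosome."""
    genes = list(chrom)
    slot = int(rng.integers(len(genes)))
    g = int(rng.integers(n_genes))
    while g in genes:
        g = int(rng.integers(n_genes))
    genes[slot] = g
    return tuple(sorted(genes))


def sa_search(
    fitness: FitnessCache,
    n_genes: int,
    params: SaParams,
    t0: float,
    rng: np.random.Generator,
) -> tuple[tuple, float, int]:
    """One annealing run; returns (best chromosome, best energy, n evals).

    Exactly ``maxit`` energy evaluations are spent: one on the random
    initial chromosome and one per proposed neighbor.
    """
    if n_genes < params.k + 1:
        raise ValueError("pool too small for the mutation operator")
    current = random_chromosome(n_genes, params.k, rng)
    e_current = 1.0 - fitness(current)
    evals = 1
    best, e_best = current, e_current
    while evals < params.maxit:
        cand = _neighbor(current, n_genes, rng)
        e_cand = 1.0 - fitness(cand)
        evals += 1
        temp = _temperature(t0, evals, params.tmax)
        if metropolis_accept(e_cand - e_current, temp, rng):
            current, e_current = cand, e_cand
            if e_current < e_best:
                best, e_best = current, e_current
    return best, e_best, evals


def run_insel(pool: RatioMatrix, params: SaParams) -> SelectionRun:
    """Collect annealing solutions and rank genes by frequency.

    ``max_solutions`` independent annealing searches are run; the returned
    best-ever chromosomes are filtered to those whose independently
    recomputed LOOCV accuracy reaches ``goal_accuracy``, and the surviving
    chromosomes are frequency-ranked exactly as in the GA stage.
    """
    X, labels = pool.matrix().T, pool.time
    fitness = FitnessCache(X, labels)
    rng = np.random.default_rng(params.seed)
    gene_ids = pool.gene_ids
    t0 = estimate_initial_temperature(fitness, len(gene_ids), params, rng)
    logger.info("INSEL calibrated starting temperature T0 = %.5f", t0)
    solutions = []
    total_evals = 0
    for _ in range(params.max_solutions):
        best, _e, n_ev = sa_search(fitness, len(gene_ids), params, t0, rng)
        total_evals += n_ev
        preds = loocv_predictions(X[:, list(best)], labels)
        if float(np.mean(preds == labels)) >= params.goal_accuracy:
            solutions.append(best)
    if not solutions:
        warnings.warn(
            "INSEL collected no chromosomes at the goal accuracy",
            stacklevel=2,
        )
    ranking = rank_by_frequency(solutions, gene_ids)
    return SelectionRun(
        method="insel_sann",
        params=params,
        solutions=[tuple(gene_ids[g] for g in c) for c in solutions],
        ranking=ranking,
        n_attempts=params.max_solutions,
        seed=params.seed,
        extras={
            "t0": t0,
            "n_unique": len(set(solutions)),
            "search_evaluations": total_evals,
        },
    )


def repeated_runs(
    pool: RatioMatrix, params: SaParams, n_runs: int = 4
) -> list[SelectionRun]:
    """Independent annealing repetitions seeded from the master seed."""
    seeds = np.random.SeedSequence(params.seed).generate_state(n_runs)
    runs = []
    for s in seeds:
        p = SaParams(**{**params.__dict__, "seed": int(s % 2**31)})
        runs.append(run_insel(pool, p))
    return runs
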