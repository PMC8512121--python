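"""Logistic-map chaotic sequences and chaotic population initialization.

The logistic map ``b_{i+1} = mu * b_i * (1 - b_i)`` with ``mu = 4`` is fully
chaotic on (0, 1): iterates are ergodic and sensitive to the seed value,
which makes the sequence a cheap source of well-spread perturbations.  The
map degenerates onto fixed points or short cycles when the seed hits
{0.25, 0.5, 0.75, 1} (0.5 maps to the fixed point 0.75 in one step; 0.25
enters the same cycle), so seeds are rejection-sampled away from that set.

Chaotic initialization doubles the initial sample: a uniform population P is
paired with a chaotic twin Pc obtained by scaling each individual by one
logistic-map value, all 2N candidates are evaluated, and the best N are kept.
This costs exactly 2N fitness evaluations and stochastically dominates plain
uniform initialization.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .problems import BoxProblem, BudgetedProblem, BudgetExhaustedError

__all__ = [
    "DEFAULT_MU",
    "EXCLUDED_SEEDS",
    "draw_valid_beta0",
    "logistic_sequence",
    "chaotic_map_population",
    "chaotic_init",
]

DEFAULT_MU = 4.0
#: Seed values on which the mu=4 logistic map collapses to fixed points/cycles.
EXCLUDED_SEEDS = (0.25, 0.5, 0.75, 1.0)
#: Absolute tolerance for the excluded-seed check; exact hits are measure-zero
#: but must not poison the sequence.
SEED_TOL = 1e-12


def _beta0_valid(beta0: float) -> bool:
    if not 0.0 < beta0 < 1.0:
        return False
    return all(abs(beta0 - bad) > SEED_TOL for bad in EXCLUDED_SEEDS)


def draw_valid_beta0(rng: np.random.Generator) -> float:
    """Draw a logistic-map seed uniformly from (0,1), excluding degenerate values.

    Rejection-resampled until valid; the excluded set has measure zero so the
    loop terminates with probability one (and in practice immediately).
    """
    while True:
        beta0 = float(rng.random())
        if _beta0_valid(beta0):
            return beta0


def logistic_sequence(beta0: float, n: int, mu: float = DEFAULT_MU) -> np.ndarray:
    """Iterate the logistic map ``n`` times starting from ``beta0``.

    Returns an array of length ``n`` whose first element is ``beta0`` itself.
    """
    if n < 1:
        raise ValueError("sequence length must be at least 1")
    if not _beta0_valid(beta0):
        raise ValueError(
            f"beta0 must lie strictly in (0,1) and avoid {EXCLUDED_SEEDS} "
            f"(within {SEED_TOL:g}); got {beta0!r}"
        )
    seq = np.empty(n)
    b = beta0
    seq[0] = b
    for i in range(1, n):
        b = mu * b * (1.0 - b)
        seq[i] = b
    return seq


def chaotic_map_population(
    positions: np.ndarray,
    sequence: np.ndarray,
    lower: Optional[np.ndarray] = None,
    upper: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Scale each individual by one chaotic value: ``Xc_i = beta_i * X_i``.

    One scalar of ``sequence`` multiplies every coordinate of the matching
    row of ``positions``.  When bounds are given the result is clamped into
    the box (scaling can leave it when lower > 0 or bounds are asymmetric).
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    sequence = np.asarray(sequence, dtype=float)
    if sequence.shape[0] < positions.shape[0]:
        raise ValueError(
            f"chaotic sequence of length {sequence.shape[0]} is shorter than "
            f"the population of size {positions.shape[0]}"
        )
    mapped = positions * sequence[: positions.shape[0], None]
    if lower is not None and upper is not None:
        mapped = np.clip(mapped, lower, upper)
    return mapped


def chaotic_init(
    budget: BudgetedProblem,
    n: int,
    rng: np.random.Generator,
    mu: float = DEFAULT_MU,
) -> tuple[np.ndarray, np.ndarray]:
    """Chaotically seeded initial population of size ``n``.

    Draws a uniform population P, builds its chaotic twin Pc by per-individual
    logistic scaling, evaluates all 2n candidates and keeps the n best.
    Consumes exactly ``2 * n`` FFEs.

    Returns ``(positions, fitness)`` with shapes (n, D) and (n,).
    """
    problem: BoxProblem = budget.problem
    if budget.accounting == "all" and budget.remaining < 2 * n:
        raise BudgetExhaustedError(
            f"chaotic initialization needs {2 * n} FFEs but only "
            f"{budget.remaining} remain"
        )
    uniform = problem.uniform(rng, n)
    beta0 = draw_valid_beta0(rng)
    seq = logistic_sequence(beta0, n, mu)
    twins = chaotic_map_population(uniform, seq, problem.lower, problem.upper)
    pool = np.vstack([uniform, twins])
    fitness = np.array([budget.evaluate(x) for x in pool])
    order = np.argsort(fitness, kind="stable")[:n]
    return pool[order].copy(), fitness[order].copy()


def uniform_init(
    budget: BudgetedProblem, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Plain uniform initialization; consumes exactly ``n`` FFEs."""
    if budget.accounting == "all" and budget.remaining < n:
        raise BudgetExhaustedError(
            f"uniform initialization needs {n} FFEs but only "
            f"{budget.remaining} remain"
        )
    positions = budget.problem.uniform(rng, n)
    fitness = np.array([budget.evaluate(x) for x in positions])
    return positions, fitness
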