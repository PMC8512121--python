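"""Harris Hawks optimization: update operators and the main loop.

HHO mimics the cooperative surprise pounce of Harris' hawks.  A scalar
*escape energy* ``E = 2*E0*(1 - ffes/max_ffes)`` (E0 resampled in [-1, 1]
per hawk per update) schedules the search: while |E| >= 1 hawks explore, and
once |E| < 1 they exploit the incumbent best ("prey") through four besiege
modes chosen by |E| and a fresh uniform draw r:

========================  =========================================
r >= 0.5, 0.5 <= |E| < 1  soft besiege (encircle the tiring prey)
r >= 0.5, |E| < 0.5       hard besiege (pounce on the exhausted prey)
r < 0.5, 0.5 <= |E| < 1   soft besiege with progressive rapid dives
r < 0.5, |E| < 0.5        hard besiege with rapid dives (team average)
========================  =========================================

The dive modes propose up to two candidates (the second offset by a
heavy-tailed Levy flight) and accept greedily, spending up to two extra
fitness evaluations; all evaluations are charged to the FFE budget under the
default ``all`` accounting.

All random multipliers (q, r, r1..r5, E0, J) are scalars per hawk per
update; positions leaving the box are clamped componentwise.
"""

from __future__ import annotations

import math
from typing import Callable, Optional

import numpy as np

from .problems import BoxProblem, BudgetedProblem, RunRecord

__all__ = [
    "LEVY_BETA",
    "escape_energy",
    "jump_strength",
    "levy_sigma",
    "levy_flight",
    "mean_position",
    "exploration_update",
    "soft_besiege",
    "hard_besiege",
    "soft_besiege_dives",
    "hard_besiege_dives",
    "run_hho",
]

#: Stability exponent of the Levy-flight step generator (Mantegna method).
LEVY_BETA = 1.5


def escape_energy(e0: float, ffes: int, max_ffes: int) -> float:
    """Prey escape energy ``2*E0*(1 - ffes/max_ffes)``; decays to 0 at budget end."""
    if max_ffes <= 0:
        raise ValueError("max_ffes must be positive")
    if not 0 <= ffes <= max_ffes:
        raise ValueError("ffes must lie in [0, max_ffes]")
    return 2.0 * e0 * (1.0 - ffes / max_ffes)


def jump_strength(rng: np.random.Generator) -> float:
    """Random jump strength ``J = 2*(1 - r5)`` in [0, 2] (prey zig-zag)."""
    return 2.0 * (1.0 - rng.random())


def levy_sigma(beta: float = LEVY_BETA) -> float:
    """Mantegna scale sigma(beta) for Levy-stable step generation."""
    num = math.gamma(1.0 + beta) * math.sin(math.pi * beta / 2.0)
    den = math.gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return (num / den) ** (1.0 / beta)


def levy_flight(
    d: int, rng: np.random.Generator, beta: float = LEVY_BETA, scale: float = 0.01
) -> np.ndarray:
    """Heavy-tailed step vector ``scale * u * sigma / |v|**(1/beta)``.

    u and v are independent standard-normal vectors of length ``d`` (u is
    drawn first, then v — the order is part of the reproducibility contract).
    """
    sigma = levy_sigma(beta)
    u = rng.standard_normal(d)
    v = rng.standard_normal(d)
    return scale * u * sigma / np.abs(v) ** (1.0 / beta)


def mean_position(positions: np.ndarray) -> np.ndarray:
    """Coordinatewise arithmetic mean of the population."""
    positions = np.atleast_2d(positions)
    if positions.shape[0] == 0:
        raise ValueError("population is empty")
    return positions.mean(axis=0)


def exploration_update(
    x: np.ndarray,
    positions: np.ndarray,
    best: np.ndarray,
    xm: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exploration move: perch on a random member or inside the team's range.

    With probability 1/2 the hawk moves relative to a uniformly chosen
    population member, otherwise relative to the best-minus-mean direction
    with a random point of the box subtracted.  Draw order: q, then the
    member index (first branch) or r3, r4 (second branch), then r1, r2.
    """
    q = rng.random()
    if q >= 0.5:
        idx = int(rng.integers(positions.shape[0]))
        x_rand = positions[idx]
        r1 = rng.random()
        r2 = rng.random()
        new = x_rand - r1 * np.abs(x_rand - 2.0 * r2 * x)
    else:
        r3 = rng.random()
        r4 = rng.random()
        new = (best - xm) - r3 * (lower + r4 * (upper - lower))
    return np.clip(new, lower, upper)


def soft_besiege(
    x: np.ndarray,
    best: np.ndarray,
    e: float,
    j: float,
    lower: np.ndarray,
    upper: np.ndarray,
) -> np.ndarray:
    """Soft besiege: ``(Xbest - X) - E*|J*Xbest - X|``, clamped."""
    delta = best - x
    new = delta - e * np.abs(j * best - x)
    return np.clip(new, lower, upper)


def hard_besiege(
    x: np.ndarray,
    best: np.ndarray,
    e: float,
    lower: np.ndarray,
    upper: np.ndarray,
) -> np.ndarray:
    """Hard besiege: ``Xbest - E*|Xbest - X|``, clamped."""
    new = best - e * np.abs(best - x)
    return np.clip(new, lower, upper)


def _dive(
    x: np.ndarray,
    fx: float,
    y: np.ndarray,
    budget: BudgetedProblem,
    rng: np.random.Generator,
    lower: np.ndarray,
    upper: np.ndarray,
) -> tuple[np.ndarray, float, int, bool]:
    """Greedy rapid-dive acceptance shared by both dive operators.

    Evaluates the first candidate Y; if it does not improve on the hawk,
    a second candidate ``Z = Y + S * LF(D)`` (S uniform in [0,1)^D, drawn
    before the Levy vector) is tried.  Returns (position, fitness,
    evaluations spent, truncated-by-budget flag).  Short-circuits: Z is not
    evaluated when Y already improves.
    """
    d = x.shape[0]
    if budget.accounting == "all" and budget.remaining < 1:
        return x, fx, 0, True
    y = np.clip(y, lower, upper)
    fy = budget.evaluate(y)
    if fy < fx:
        return y, fy, 1, False
    s = rng.random(d)
    z = np.clip(y + s * levy_flight(d, rng), lower, upper)
    if budget.accounting == "all" and budget.remaining < 1:
        return x, fx, 1, True
    fz = budget.evaluate(z)
    if fz < fx:
        return z, fz, 2, False
    return x, fx, 2, False


def soft_besiege_dives(
    x: np.ndarray,
    fx: float,
    best: np.ndarray,
    e: float,
    j: float,
    budget: BudgetedProblem,
    rng: np.random.Generator,
    lower: np.ndarray,
    upper: np.ndarray,
) -> tuple[np.ndarray, float, int, bool]:
    """Soft besiege with progressive rapid dives (greedy, up to 2 FFEs)."""
    y = best - e * np.abs(j * best - x)
    return _dive(x, fx, y, budget, rng, lower, upper)


def hard_besiege_dives(
    x: np.ndarray,
    fx: float,
    best: np.ndarray,
    xm: np.ndarray,
    e: float,
    j: float,
    budget: BudgetedProblem,
    rng: np.random.Generator,
    lower: np.ndarray,
    upper: np.ndarray,
) -> tuple[np.ndarray, float, int, bool]:
    """Hard besiege with rapid dives: Y targets the team mean distance."""
    y = best - e * np.abs(j * best - xm)
    return _dive(x, fx, y, budget, rng, lower, upper)


ReplacementHook = Callable[
    [np.ndarray, np.ndarray, BudgetedProblem, np.random.Generator], None
]
InitFn = Callable[
    [BudgetedProblem, int, np.random.Generator], tuple[np.ndarray, np.ndarray]
]


def _engine(
    budget: BudgetedProblem,
    n: int,
    rng: np.random.Generator,
    init: InitFn,
    init_cost: int,
    replacement: Optional[ReplacementHook],
    algorithm: str,
) -> RunRecord:
    """Shared HHO/eHHO main loop over a budgeted problem."""
    problem = budget.problem
    lower, upper = problem.lower, problem.upper
    max_ffes = budget.max_ffes
    per_iter_cost = n + (1 if replacement is not None else 0)

    if budget.accounting == "per_iteration":
        budget.charge(init_cost)
    positions, fitness = init(budget, n, rng)
    truncated = False
    iterations = 0

    while not budget.exhausted:
        if budget.accounting == "per_iteration":
            if budget.remaining < per_iter_cost:
                break
            budget.charge(per_iter_cost)
        iterations += 1
        ibest = int(np.argmin(fitness))
        best = positions[ibest].copy()
        fbest = fitness[ibest]
        xm = mean_position(positions)
        for i in range(n):
            if budget.accounting == "all" and budget.remaining < 1:
                truncated = True
                break
            x = positions[i]
            fx = fitness[i]
            e0 = rng.uniform(-1.0, 1.0)
            e = escape_energy(e0, min(budget.ffes, max_ffes), max_ffes)
            j = jump_strength(rng)
            if abs(e) >= 1.0:
                new = exploration_update(x, positions, best, xm, lower, upper, rng)
                fnew = budget.evaluate(new)
            else:
                r = rng.random()
                if r >= 0.5 and abs(e) >= 0.5:
                    new = soft_besiege(x, best, e, j, lower, upper)
                    fnew = budget.evaluate(new)
                elif r >= 0.5:
                    new = hard_besiege(x, best, e, lower, upper)
                    fnew = budget.evaluate(new)
                elif abs(e) >= 0.5:
                    new, fnew, _, trunc = soft_besiege_dives(
                        x, fx, best, e, j, budget, rng, lower, upper
                    )
                    truncated = truncated or trunc
                else:
                    new, fnew, _, trunc = hard_besiege_dives(
                        x, fx, best, xm, e, j, budget, rng, lower, upper
                    )
                    truncated = truncated or trunc
            positions[i] = new
            fitness[i] = fnew
            if fnew < fbest:
                best = positions[i].copy()
                fbest = fnew
        if replacement is not None and not budget.exhausted:
            replacement(positions, fitness, budget, rng)
    return RunRecord.from_budget(budget, algorithm, iterations, truncated)


def run_hho(
    problem: BoxProblem,
    n: int,
    max_ffes: int,
    rng: np.random.Generator | int,
    accounting: str = "all",
) -> RunRecord:
    """Run basic HHO with population ``n`` under an FFE budget.

    Initialization is plain uniform (n FFEs); the loop then applies the
    exploration/besiege operators per hawk until the budget is exhausted.
    """
    from .chaos import uniform_init

    if max_ffes <= n:
        raise ValueError("max_ffes must exceed the population size")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    budget = BudgetedProblem(problem, max_ffes, accounting)
    return _engine(budget, n, rng, uniform_init, n, None, "hho")
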