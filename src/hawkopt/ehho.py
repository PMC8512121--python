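"""Enhanced HHO: quasi-reflection replacement, chaotic best-search, controller.

Three additions to basic HHO:

1. **Chaotic initialization** (see :mod:`hawkopt.chaos`): the starting
   population is the best half of a uniform sample and its logistic-map twin,
   at a cost of 2N evaluations.
2. **Quasi-reflection-based learning (QRL)**: a candidate is drawn uniformly,
   per coordinate, between the box midpoint and the incumbent best — the
   "quasi-reflexive opposite" of the best solution.
3. **Chaotic best-search (CS)**: when QRL stagnates, a candidate is blended
   between the best and a logistic-map point of the box, with a shrinkage
   weight ``theta = (max_ffes - ffes + 1)/max_ffes`` that narrows the search
   radius as the budget is spent.

One replacement step runs per iteration, after the hawk updates, costing one
extra evaluation.  An FFE threshold ``psi`` and a stagnation threshold ``bt``
pick the strategy:

* ``psi < ffes``     — QRL candidate challenges the current *worst* hawk;
* ``k < bt``         — QRL candidate challenges the *best* (k counts failures);
* otherwise          — CS candidate challenges the best.

Acceptance is always greedy on strict improvement; a successful challenge of
the best resets the stagnation counter k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chaos import chaotic_init, draw_valid_beta0, logistic_sequence
from .problems import BoxProblem, BudgetedProblem, RunRecord

__all__ = [
    "EHHOControl",
    "quasi_reflect",
    "shrink_theta",
    "chaotic_best_candidate",
    "replacement_step",
    "default_psi",
    "default_bt",
    "run_ehho",
]


@dataclass
class EHHOControl:
    """Adaptive-controller state for the replacement step.

    ``psi`` is an FFE-count threshold, ``bt`` the stagnation threshold, and
    ``k`` the running count of consecutive failed best-improvements.  Branch
    trigger counts are kept for diagnostics (and reachability tests).
    """

    psi: int
    bt: int
    k: int = 0
    branch_counts: dict = field(
        default_factory=lambda: {"replace_worst": 0, "qrl_best": 0, "chaotic_best": 0}
    )

    def __post_init__(self) -> None:
        if self.psi < 0:
            raise ValueError("psi must be non-negative")
        if self.bt < 1:
            raise ValueError("bt must be at least 1")


def quasi_reflect(
    position: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Quasi-reflexive opposite: uniform per coordinate between midpoint and x.

    The interval is order-agnostic — for coordinates left of the midpoint the
    draw lies in [x_j, m_j], otherwise in [m_j, x_j].
    """
    mid = 0.5 * (lower + upper)
    return mid + rng.random(position.shape[0]) * (position - mid)


def shrink_theta(ffes: int, max_ffes: int) -> float:
    """Dynamic shrinkage ``(max_ffes - ffes + 1)/max_ffes``, decreasing in ffes."""
    if not 1 <= ffes <= max_ffes:
        raise ValueError("ffes must lie in [1, max_ffes]")
    return (max_ffes - ffes + 1) / max_ffes


def chaotic_best_candidate(
    best: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    theta: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Blend the best with a fresh logistic-map point of the box.

    A new per-dimension chaotic sequence spans the box, ``S = LB + beta*(UB-LB)``,
    and the candidate ``(1-theta)*best + theta*S`` stays in the box by
    convexity: pure chaotic point at theta=1, pure best as theta -> 0.
    """
    if not 0.0 < theta <= 1.0:
        raise ValueError("theta must lie in (0, 1]")
    beta0 = draw_valid_beta0(rng)
    beta = logistic_sequence(beta0, best.shape[0])
    s = lower + beta * (upper - lower)
    return (1.0 - theta) * best + theta * s


def replacement_step(
    positions: np.ndarray,
    fitness: np.ndarray,
    control: EHHOControl,
    budget: BudgetedProblem,
    rng: np.random.Generator,
) -> None:
    """One controller-selected QRL/CS replacement; costs exactly one FFE.

    Mutates ``positions``/``fitness`` in place under greedy (strict) acceptance.
    A no-op when the budget is already exhausted.
    """
    if budget.accounting == "all" and budget.remaining < 1:
        return
    problem: BoxProblem = budget.problem
    lower, upper = problem.lower, problem.upper
    ibest = int(np.argmin(fitness))
    best = positions[ibest]

    if control.psi < budget.ffes:
        control.branch_counts["replace_worst"] += 1
        candidate = quasi_reflect(best, lower, upper, rng)
        f = budget.evaluate(candidate)
        iworst = int(np.argmax(fitness))
        if f < fitness[iworst]:
            positions[iworst] = candidate
            fitness[iworst] = f
    elif control.k < control.bt:
        control.branch_counts["qrl_best"] += 1
        candidate = quasi_reflect(best, lower, upper, rng)
        f = budget.evaluate(candidate)
        if f < fitness[ibest]:
            positions[ibest] = candidate
            fitness[ibest] = f
            control.k = 0
        else:
            control.k += 1
    else:
        control.branch_counts["chaotic_best"] += 1
        theta = shrink_theta(max(budget.ffes, 1), budget.max_ffes)
        candidate = chaotic_best_candidate(best, lower, upper, theta, rng)
        f = budget.evaluate(candidate)
        if f < fitness[ibest]:
            positions[ibest] = candidate
            fitness[ibest] = f
            control.k = 0


def _round_half_up(x: float) -> int:
    """Round to the nearest integer with halves away from zero."""
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def default_psi(max_ffes: int) -> int:
    """Default FFE threshold: a quarter of the budget."""
    if max_ffes <= 0:
        raise ValueError("max_ffes must be positive")
    return _round_half_up(max_ffes / 4)


def default_bt(max_ffes: int, psi: int, n: int, variant: str = "benchmark") -> int:
    """Default stagnation threshold.

    ``benchmark`` variant: round((max_ffes - psi)/(10*n)) — tuned for long
    analytic-benchmark budgets.  ``cnn`` variant: round((max_ffes - psi)/n) —
    for short design-search budgets.  Results below 1 are clamped to 1.
    """
    if max_ffes <= psi:
        raise ValueError("max_ffes must exceed psi")
    if n < 1:
        raise ValueError("population size must be at least 1")
    if variant == "benchmark":
        bt = _round_half_up((max_ffes - psi) / (10 * n))
    elif variant == "cnn":
        bt = _round_half_up((max_ffes - psi) / n)
    else:
        raise ValueError("variant must be 'benchmark' or 'cnn'")
    if bt < 1:
        import warnings

        warnings.warn("computed bt below 1; clamped to 1", stacklevel=2)
        bt = 1
    return bt


def run_ehho(
    problem: BoxProblem,
    n: int,
    max_ffes: int,
    rng: np.random.Generator | int,
    psi: int | str = "auto",
    bt: int | str = "auto",
    accounting: str = "all",
    variant: str = "benchmark",
) -> RunRecord:
    """Run enhanced HHO: chaotic init + hawk updates + one replacement per iteration.

    ``psi``/``bt`` accept ``"auto"`` to apply the default formulas.  Returns a
    :class:`~hawkopt.problems.RunRecord`; the attached ``control`` attribute
    exposes the controller state (branch trigger counts, final k).
    """
    from .hho import _engine

    if max_ffes <= 2 * n:
        raise ValueError("max_ffes must exceed 2*n (chaotic init cost)")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    psi_val = default_psi(max_ffes) if psi == "auto" else int(psi)
    bt_val = default_bt(max_ffes, psi_val, n, variant) if bt == "auto" else int(bt)
    control = EHHOControl(psi=psi_val, bt=bt_val)
    budget = BudgetedProblem(problem, max_ffes, accounting)

    def hook(positions, fitness, budget_, rng_):
        replacement_step(positions, fitness, control, budget_, rng_)

    record = _engine(budget, n, rng, chaotic_init, 2 * n, hook, "ehho")
    record.control = control  # diagnostics; not part of the dataclass contract
    return record
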