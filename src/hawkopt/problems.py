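"""Box-constrained minimization problems and fitness-evaluation budgets.

All optimizers in this package are budgeted in *fitness function evaluations*
(FFEs), not iterations: one FFE is one call to the objective.  Comparing
algorithms at an equal FFE budget is the only fair accounting when different
algorithms spend a different number of evaluations per iteration.

Two accounting modes are supported:

``all``
    Every objective call is charged against the budget (honest accounting;
    the default).  Termination is checked before each evaluation, so a
    partially updated final iteration is allowed.
``per_iteration``
    The budget clock advances by a fixed amount per iteration (the textbook
    idealization of population-based optimizers: N evaluations per iteration,
    N+1 when a replacement step is attached).  Actual evaluations are still
    counted separately for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "BoxProblem",
    "BudgetedProblem",
    "BudgetExhaustedError",
    "RunRecord",
    "clamp",
]


class BudgetExhaustedError(RuntimeError):
    """Raised when an evaluation is requested beyond the FFE budget."""


@dataclass
class BoxProblem:
    """A minimization problem over an axis-aligned box.

    Parameters
    ----------
    name : str
        Identifier used in result tables.
    dimension : int
        Number of decision variables ``D``.
    lower, upper : ndarray of shape (D,)
        Componentwise bounds, ``lower < upper``.
    objective : callable
        Maps a position vector of shape (D,) to a scalar fitness (minimized).
    known_optimum : float, optional
        Reference value of the global minimum, when analytically known.
    """

    name: str
    dimension: int
    lower: np.ndarray
    upper: np.ndarray
    objective: Callable[[np.ndarray], float]
    known_optimum: Optional[float] = None

    def __post_init__(self) -> None:
        self.lower = np.broadcast_to(
            np.asarray(self.lower, dtype=float), (self.dimension,)
        ).copy()
        self.upper = np.broadcast_to(
            np.asarray(self.upper, dtype=float), (self.dimension,)
        ).copy()
        if not np.all(self.lower < self.upper):
            raise ValueError("lower bounds must be strictly below upper bounds")

    def clamp(self, x: np.ndarray) -> np.ndarray:
        """Project ``x`` componentwise into the box."""
        return np.clip(x, self.lower, self.upper)

    def uniform(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Sample ``n`` positions uniformly in the box, shape (n, D)."""
        span = self.upper - self.lower
        return self.lower + span * rng.random((n, self.dimension))


def clamp(x: np.ndarray, lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    return np.clip(x, lower, upper)


class BudgetedProblem:
    """Wraps a :class:`BoxProblem` with an FFE budget and best-so-far log.

    The wrapper is the single gateway through which optimizers evaluate the
    objective, so budget conservation and the monotone best-so-far trajectory
    are enforced structurally rather than by convention.
    """

    def __init__(
        self,
        problem: BoxProblem,
        max_ffes: int,
        accounting: str = "all",
    ) -> None:
        if max_ffes <= 0:
            raise ValueError("max_ffes must be positive")
        if accounting not in ("all", "per_iteration"):
            raise ValueError("accounting must be 'all' or 'per_iteration'")
        self.problem = problem
        self.max_ffes = int(max_ffes)
        self.accounting = accounting
        self.evaluations = 0  # actual objective calls
        self._clock = 0  # budget clock (== evaluations in 'all' mode)
        self.best_fitness = np.inf
        self.best_position: Optional[np.ndarray] = None
        self.trajectory: list[tuple[int, float]] = []

    # -- budget clock -----------------------------------------------------
    @property
    def ffes(self) -> int:
        """Current position of the budget clock."""
        return self._clock

    @property
    def remaining(self) -> int:
        return self.max_ffes - self._clock

    @property
    def exhausted(self) -> bool:
        return self._clock >= self.max_ffes

    def charge(self, n: int) -> None:
        """Advance the budget clock by ``n`` (used by per-iteration mode)."""
        self._clock += int(n)

    # -- evaluation -------------------------------------------------------
    def evaluate(self, x: np.ndarray) -> float:
        """Evaluate the objective at ``x``, charging the budget.

        In ``all`` mode raises :class:`BudgetExhaustedError` when no budget
        remains; in ``per_iteration`` mode evaluations are individually free
        (the caller charges the clock per iteration).
        """
        if self.accounting == "all":
            if self.exhausted:
                raise BudgetExhaustedError(
                    f"FFE budget of {self.max_ffes} exhausted for "
                    f"problem {self.problem.name!r}"
                )
            self._clock += 1
        self.evaluations += 1
        f = float(self.problem.objective(np.asarray(x, dtype=float)))
        if f < self.best_fitness:
            self.best_fitness = f
            self.best_position = np.array(x, dtype=float, copy=True)
        self.trajectory.append((self._clock, self.best_fitness))
        return f


@dataclass
class RunRecord:
    """Outcome of one optimizer run.

    ``trajectory`` holds (ffes, best-so-far fitness) pairs, one per objective
    evaluation, and is monotone non-increasing in its second component.
    """

    problem: str
    algorithm: str
    best_position: np.ndarray
    best_fitness: float
    ffes_used: int
    evaluations: int
    iterations: int
    trajectory: list[tuple[int, float]] = field(repr=False, default_factory=list)
    truncated: bool = False

    @classmethod
    def from_budget(
        cls,
        budget: BudgetedProblem,
        algorithm: str,
        iterations: int,
        truncated: bool = False,
    ) -> "RunRecord":
        return cls(
            problem=budget.problem.name,
            algorithm=algorithm,
            best_position=budget.best_position,
            best_fitness=budget.best_fitness,
            ffes_used=budget.ffes,
            evaluations=budget.evaluations,
            iterations=iterations,
            trajectory=budget.trajectory,
            truncated=truncated,
        )
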