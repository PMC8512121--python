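"""Multi-run experiment harness over problems x algorithms.

An *algorithm* here is any callable ``(problem, seed) -> RunRecord``; factory
helpers wrap the package's optimizers and a uniform random-search baseline.
Each (problem, algorithm, run) triple gets the seed ``base_seed + run``, so
every algorithm sees the same seed list and paired comparisons are honest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ehho import run_ehho
from .hho import run_hho
from .problems import BoxProblem, BudgetedProblem, RunRecord
from .ranking import ResultTable

__all__ = [
    "AlgorithmRunner",
    "ExperimentResult",
    "random_search",
    "hho_runner",
    "ehho_runner",
    "random_search_runner",
    "run_experiment",
]

AlgorithmRunner = Callable[[BoxProblem, int], RunRecord]


def random_search(
    problem: BoxProblem, max_ffes: int, rng: np.random.Generator | int
) -> RunRecord:
    """Uniform random search at an equal FFE budget (the honesty baseline)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    budget = BudgetedProblem(problem, max_ffes)
    while not budget.exhausted:
        x = problem.uniform(rng, 1)[0]
        budget.evaluate(x)
    return RunRecord.from_budget(budget, "random_search", iterations=max_ffes)


def hho_runner(n: int, max_ffes: int, accounting: str = "all") -> AlgorithmRunner:
    def run(problem: BoxProblem, seed: int) -> RunRecord:
        return run_hho(problem, n, max_ffes, np.random.default_rng(seed), accounting)

    return run


def ehho_runner(
    n: int,
    max_ffes: int,
    psi: int | str = "auto",
    bt: int | str = "auto",
    accounting: str = "all",
    variant: str = "benchmark",
) -> AlgorithmRunner:
    def run(problem: BoxProblem, seed: int) -> RunRecord:
        return run_ehho(
            problem, n, max_ffes, np.random.default_rng(seed),
            psi=psi, bt=bt, accounting=accounting, variant=variant,
        )

    return run


def random_search_runner(max_ffes: int) -> AlgorithmRunner:
    def run(problem: BoxProblem, seed: int) -> RunRecord:
        return random_search(problem, max_ffes, np.random.default_rng(seed))

    return run


@dataclass
class ExperimentResult:
    """Mean/std tables plus raw per-run finals and failure flags."""

    table: ResultTable
    raw: dict = field(repr=False, default_factory=dict)
    failures: list = field(default_factory=list)
    records: dict = field(repr=False, default_factory=dict)


def run_experiment(
    algorithms: Mapping[str, AlgorithmRunner],
    problems: Sequence[BoxProblem],
    runs: int,
    base_seed: int = 0,
    keep_records: bool = False,
) -> ExperimentResult:
    """Run every algorithm on every problem ``runs`` times with shared seeds.

    A run that raises is recorded as a failure and leaves a NaN cell; the
    resulting table is then rejected by the statistics (which require finite
    cells), so failures cannot silently distort a comparison.
    """
    names = list(algorithms)
    prob_names = [p.name for p in problems]
    means = pd.DataFrame(index=prob_names, columns=names, dtype=float)
    stds = pd.DataFrame(index=prob_names, columns=names, dtype=float)
    raw: dict = {}
    records: dict = {}
    failures = []
    for problem in problems:
        for name, runner in algorithms.items():
            finals = []
            for run_idx in range(runs):
                seed = base_seed + run_idx
                try:
                    rec = runner(problem, seed)
                except Exception as exc:  # noqa: BLE001 - failures are data here
                    failures.append((problem.name, name, seed, repr(exc)))
                    continue
                finals.append(rec.best_fitness)
                if keep_records:
                    records.setdefault((problem.name, name), []).append(rec)
            raw[(problem.name, name)] = finals
            if finals:
                means.loc[problem.name, name] = float(np.mean(finals))
                stds.loc[problem.name, name] = float(np.std(finals, ddof=1)) if len(finals) > 1 else 0.0

    try:
        table = ResultTable(mean=means, std=stds)
    except ValueError:
        # failed runs leave NaN cells; keep the frames but let the statistics
        # reject the table loudly if it is ever passed to them
        table = ResultTable.__new__(ResultTable)
        table.mean = means
        table.std = stds
    return ExperimentResult(table=table, raw=raw, failures=failures, records=records)
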