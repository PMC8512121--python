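"""Enhancement operators, the psi/bt controller and the full enhanced loop."""

import numpy as np
import pytest

from hawkopt.benchmarks import make_builtin
from hawkopt.ehho import (
    EHHOControl,
    chaotic_best_candidate,
    default_bt,
    default_psi,
    quasi_reflect,
    replacement_step,
    run_ehho,
    shrink_theta,
)
from hawkopt.hho import run_hho
from hawkopt.problems import BoxProblem, BudgetedProblem


# -- quasi-reflection ---------------------------------------------------------

def test_quasi_reflect_lands_between_midpoint_and_position(rng):
    lb, ub = np.full(4, -4.0), np.full(4, 4.0)
    x = np.array([2.0, -3.0, 0.0, 4.0])
    for _ in range(200):
        out = quasi_reflect(x, lb, ub, rng)
        assert np.all(out >= np.minimum(0.0, x) - 1e-12)
        assert np.all(out <= np.maximum(0.0, x) + 1e-12)
    # midpoint coordinate is a fixed point
    assert quasi_reflect(np.zeros(4), lb, ub, rng)[2] == 0.0


def test_quasi_reflect_uniform_mean(rng):
    lb, ub = np.zeros(1), np.full(1, 10.0)
    x = np.array([8.0])
    draws = np.array([quasi_reflect(x, lb, ub, rng)[0] for _ in range(10_000)])
    # uniform on [5, 8]: mean 6.5, sd sqrt(3)/2/sqrt(3) -> se of mean
    se = 3.0 / np.sqrt(12.0) / np.sqrt(draws.size)
    assert abs(draws.mean() - 6.5) < 3 * se


# -- shrinkage schedule -------------------------------------------------------

@pytest.mark.parametrize(
    "ffes, max_ffes, expected",
    [(1, 100, 1.0), (100, 100, 0.01), (12_500, 25_000, 0.50004)],
)
def test_shrink_theta_values(ffes, max_ffes, expected):
    assert shrink_theta(ffes, max_ffes) == pytest.approx(expected)


def test_shrink_theta_strictly_decreasing():
    vals = [shrink_theta(f, 1000) for f in range(1, 1001)]
    assert all(b < a for a, b in zip(vals, vals[1:]))


# -- chaotic best-search ------------------------------------------------------

def test_chaotic_best_candidate_limits_and_containment(rng):
    lb, ub = np.full(5, -4.0), np.full(5, 4.0)
    best = np.array([1.0, -2.0, 0.5, 3.0, -3.5])
    for theta in (1e-9, 0.3, 1.0):
        cand = chaotic_best_candidate(best, lb, ub, max(theta, 1e-9), rng)
        assert np.all((cand >= lb) & (cand <= ub))
    # theta -> 0 collapses onto the best
    cand = chaotic_best_candidate(best, lb, ub, 1e-12, rng)
    np.testing.assert_allclose(cand, best, atol=1e-10)


def test_chaotic_best_candidate_theta_one_is_pure_chaotic_point():
    rng = np.random.default_rng(5)
    lb, ub = np.zeros(3), np.full(3, 2.0)
    best = np.array([1.7, 1.7, 1.7])
    cand = chaotic_best_candidate(best, lb, ub, 1.0, rng)
    # reconstruct the chaotic point from the same stream
    from hawkopt.chaos import draw_valid_beta0, logistic_sequence

    r = np.random.default_rng(5)
    beta = logistic_sequence(draw_valid_beta0(r), 3)
    np.testing.assert_allclose(cand, lb + beta * (ub - lb))


# -- controller branching -----------------------------------------------------

def _flat_problem(value=1.0):
    return BoxProblem("flat", 2, [-1, -1], [1, 1], lambda x: value)


def test_replacement_psi_zero_always_replaces_worst():
    budget = BudgetedProblem(_flat_problem(), 100)
    budget.evaluate(np.zeros(2))  # ffes must exceed psi=0
    control = EHHOControl(psi=0, bt=3)
    pos = np.zeros((4, 2))
    fit = np.full(4, 1.0)
    for _ in range(10):
        replacement_step(pos, fit, control, budget, np.random.default_rng(0))
    assert control.branch_counts["replace_worst"] == 10
    assert control.branch_counts["qrl_best"] == 0
    assert control.branch_counts["chaotic_best"] == 0


def test_replacement_psi_at_budget_never_replaces_worst():
    budget = BudgetedProblem(_flat_problem(), 50)
    control = EHHOControl(psi=50, bt=2)
    pos = np.zeros((4, 2))
    fit = np.full(4, 1.0)
    for _ in range(20):
        replacement_step(pos, fit, control, budget, np.random.default_rng(1))
    assert control.branch_counts["replace_worst"] == 0
    # flat fitness: QRL never improves, so k climbs to bt and CS takes over
    assert control.branch_counts["qrl_best"] == 2
    assert control.branch_counts["chaotic_best"] == 18


def test_replacement_greedy_keeps_population_on_worse_candidate():
    # objective favours the incumbent: any candidate scores worse
    problem = BoxProblem("spike", 2, [-1, -1], [1, 1],
                         lambda x: 0.0 if np.all(x == 0) else 5.0)
    budget = BudgetedProblem(problem, 50)
    control = EHHOControl(psi=50, bt=1)
    control.k = 1  # at threshold: CS branch fires
    pos = np.zeros((3, 2))
    fit = np.zeros(3)
    replacement_step(pos, fit, control, budget, np.random.default_rng(2))
    assert control.branch_counts["chaotic_best"] == 1
    np.testing.assert_array_equal(pos, np.zeros((3, 2)))


def test_replacement_exhausted_budget_is_noop():
    budget = BudgetedProblem(_flat_problem(), 1)
    budget.evaluate(np.zeros(2))
    control = EHHOControl(psi=0, bt=1)
    pos, fit = np.zeros((2, 2)), np.zeros(2)
    replacement_step(pos, fit, control, budget, np.random.default_rng(0))
    assert sum(control.branch_counts.values()) == 0


# -- default parameter formulas ----------------------------------------------

@pytest.mark.parametrize("max_ffes, expected", [(25_000, 6250), (800, 200), (4, 1)])
def test_default_psi_quarter_budget(max_ffes, expected):
    assert default_psi(max_ffes) == expected


@pytest.mark.parametrize(
    "max_ffes, psi, n, variant, expected",
    [
        (25_000, 6250, 50, "benchmark", 38),
        (800, 200, 50, "cnn", 12),
        (1_000, 0, 100, "benchmark", 1),
    ],
)
def test_default_bt_formulas(max_ffes, psi, n, variant, expected):
    assert default_bt(max_ffes, psi, n, variant) == expected


def test_default_bt_clamps_to_one_with_warning():
    with pytest.warns(UserWarning):
        assert default_bt(100, 99, 50, "benchmark") == 1


# -- full enhanced runs -------------------------------------------------------

def test_run_ehho_improves_on_initial_best(sphere10):
    rec = run_ehho(sphere10, 20, 4000, 3)
    fits = [f for _, f in rec.trajectory]
    assert rec.best_fitness <= fits[0]
    assert all(b <= a for a, b in zip(fits, fits[1:]))
    assert rec.evaluations <= 4000


def test_run_ehho_per_iteration_accounting(sphere10):
    n = 20
    rec = run_ehho(sphere10, n, 2000, 5, accounting="per_iteration")
    # 2N at initialization then N+1 per iteration
    assert (rec.ffes_used - 2 * n) % (n + 1) == 0
    assert rec.iterations == (rec.ffes_used - 2 * n) // (n + 1)


@pytest.mark.parametrize("psi_mode", ["zero", "full"])
def test_run_ehho_branch_reachability(sphere10, psi_mode):
    psi = 0 if psi_mode == "zero" else 3000
    rec = run_ehho(sphere10, 10, 3000, 9, psi=psi, bt=5)
    counts = rec.control.branch_counts
    if psi_mode == "zero":
        assert counts["qrl_best"] == 0 and counts["chaotic_best"] == 0
        assert counts["replace_worst"] > 0
    else:
        assert counts["replace_worst"] == 0
        assert counts["qrl_best"] + counts["chaotic_best"] > 0


def test_run_ehho_not_worse_than_hho_paired_seeds():
    problem = make_builtin("rastrigin", 10)
    eh = [run_ehho(problem, 30, 6000, s).best_fitness for s in range(8)]
    hh = [run_hho(problem, 30, 6000, s).best_fitness for s in range(8)]
    assert np.mean(eh) <= np.mean(hh)
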