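"""Basic HHO operators: closed-form checks, oracle equivalence, loop invariants."""

import math

import numpy as np
import pytest

from hawkopt.benchmarks import make_builtin
from hawkopt.experiments import random_search
from hawkopt.hho import (
    escape_energy,
    exploration_update,
    hard_besiege,
    hard_besiege_dives,
    jump_strength,
    levy_flight,
    levy_sigma,
    mean_position,
    run_hho,
    soft_besiege,
    soft_besiege_dives,
)
from hawkopt.problems import BudgetedProblem


# -- scalar schedules ---------------------------------------------------------

@pytest.mark.parametrize(
    "e0, ffes, max_ffes, expected",
    [(0.5, 0, 100, 1.0), (0.9, 100, 100, 0.0), (-0.8, 50, 100, -0.8)],
)
def test_escape_energy_linear_decay(e0, ffes, max_ffes, expected):
    assert escape_energy(e0, ffes, max_ffes) == pytest.approx(expected)


def test_escape_energy_rejects_bad_budget():
    with pytest.raises(ValueError):
        escape_energy(0.5, 0, 0)
    with pytest.raises(ValueError):
        escape_energy(0.5, 5, 4)


def test_jump_strength_range(rng):
    draws = np.array([jump_strength(rng) for _ in range(2000)])
    assert np.all((draws >= 0) & (draws <= 2))
    assert abs(draws.mean() - 1.0) < 0.05


# -- Levy flights -------------------------------------------------------------

def test_levy_sigma_closed_form():
    beta = 1.5
    num = math.gamma(1 + beta) * math.sin(math.pi * beta / 2)
    den = math.gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2)
    assert levy_sigma(beta) == pytest.approx((num / den) ** (1 / beta))
    assert levy_sigma(1.5) == pytest.approx(0.6966, abs=1e-4)


def test_levy_flight_tail_index(rng):
    """Hill estimator on |steps| is consistent with stability exponent 1.5."""
    steps = np.abs(np.concatenate([levy_flight(1000, rng) for _ in range(100)]))
    tail = np.sort(steps)[-2000:]
    hill = 1.0 / np.mean(np.log(tail[1:] / tail[0]))
    assert 1.2 < hill < 1.8


# -- position updates vs one-line transcriptions ------------------------------

def test_mean_position_trivials():
    np.testing.assert_allclose(
        mean_position(np.array([[1.0, 1.0], [3.0, 3.0]])), [2.0, 2.0]
    )
    single = np.array([[0.5, -2.0]])
    np.testing.assert_allclose(mean_position(single), single[0])
    with pytest.raises(ValueError):
        mean_position(np.empty((0, 2)))


def test_soft_besiege_matches_transcription(rng):
    lb, ub = np.full(2, -10.0), np.full(2, 10.0)
    for _ in range(100):
        x = rng.uniform(-10, 10, 2)
        best = rng.uniform(-10, 10, 2)
        e = rng.uniform(-1, 1)
        j = rng.uniform(0, 2)
        oracle = np.clip((best - x) - e * np.abs(j * best - x), lb, ub)
        np.testing.assert_array_equal(soft_besiege(x, best, e, j, lb, ub), oracle)
    # E = 0 degenerates to the plain difference vector
    x = np.array([1.0, 2.0])
    best = np.array([3.0, -1.0])
    np.testing.assert_allclose(soft_besiege(x, best, 0.0, 1.3, lb, ub), best - x)


def test_hard_besiege_matches_transcription(rng):
    lb, ub = np.full(3, -5.0), np.full(3, 5.0)
    for _ in range(100):
        x = rng.uniform(-5, 5, 3)
        best = rng.uniform(-5, 5, 3)
        e = rng.uniform(-1, 1)
        oracle = np.clip(best - e * np.abs(best - x), lb, ub)
        np.testing.assert_array_equal(hard_besiege(x, best, e, lb, ub), oracle)
    best = np.array([1.0, -2.0, 0.5])
    np.testing.assert_allclose(hard_besiege(best, best, 0.7, lb, ub), best)
    np.testing.assert_allclose(
        hard_besiege(np.zeros(3), best, 0.0, lb, ub), best
    )


def test_exploration_update_matches_transcription(sphere10):
    lb, ub = sphere10.lower, sphere10.upper
    positions = np.random.default_rng(3).uniform(-100, 100, (8, 10))
    best = positions[0]
    xm = positions.mean(axis=0)
    for seed in range(50):
        out = exploration_update(
            positions[1], positions, best, xm, lb, ub, np.random.default_rng(seed)
        )
        r = np.random.default_rng(seed)
        q = r.random()
        if q >= 0.5:
            x_rand = positions[int(r.integers(8))]
            r1, r2 = r.random(), r.random()
            oracle = x_rand - r1 * np.abs(x_rand - 2 * r2 * positions[1])
        else:
            r3, r4 = r.random(), r.random()
            oracle = (best - xm) - r3 * (lb + r4 * (ub - lb))
        np.testing.assert_array_equal(out, np.clip(oracle, lb, ub))
        assert np.all((out >= lb) & (out <= ub))


def test_exploration_degenerate_population_stays_in_box(sphere2):
    # identical hawks at best: the best-minus-mean branch collapses to a
    # random box offset, still clamped inside
    positions = np.tile(np.array([50.0, -50.0]), (4, 1))
    for seed in range(20):
        out = exploration_update(
            positions[0], positions, positions[0], positions.mean(axis=0),
            sphere2.lower, sphere2.upper, np.random.default_rng(seed),
        )
        assert np.all((out >= sphere2.lower) & (out <= sphere2.upper))


def _dive_oracle(problem, x, fx, y_raw, seed):
    """Independent transcription of the greedy rapid-dive rule."""
    r = np.random.default_rng(seed)
    y = np.clip(y_raw, problem.lower, problem.upper)
    fy = problem.objective(y)
    if fy < fx:
        return y, fy
    d = x.shape[0]
    s = r.random(d)
    sigma = levy_sigma()
    u = r.standard_normal(d)
    v = r.standard_normal(d)
    lf = 0.01 * u * sigma / np.abs(v) ** (1 / 1.5)
    z = np.clip(y + s * lf, problem.lower, problem.upper)
    fz = problem.objective(z)
    if fz < fx:
        return z, fz
    return x, fx


@pytest.mark.parametrize("hard", [False, True])
def test_dive_operators_match_oracle_on_shared_stream(sphere2, hard):
    gen = np.random.default_rng(99)
    for seed in range(40):
        x = gen.uniform(-100, 100, 2)
        best = gen.uniform(-100, 100, 2)
        xm = gen.uniform(-100, 100, 2)
        fx = sphere2.objective(x)
        e = gen.uniform(-1, 1)
        j = gen.uniform(0, 2)
        budget = BudgetedProblem(sphere2, 10)
        if hard:
            pos, f, spent, trunc = hard_besiege_dives(
                x, fx, best, xm, e, j, budget, np.random.default_rng(seed),
                sphere2.lower, sphere2.upper,
            )
            y_raw = best - e * np.abs(j * best - xm)
        else:
            pos, f, spent, trunc = soft_besiege_dives(
                x, fx, best, e, j, budget, np.random.default_rng(seed),
                sphere2.lower, sphere2.upper,
            )
            y_raw = best - e * np.abs(j * best - x)
        opos, of = _dive_oracle(sphere2, x, fx, y_raw, seed)
        np.testing.assert_array_equal(pos, opos)
        assert f == of
        assert not trunc
        assert spent == budget.evaluations <= 2


def test_dive_keeps_hawk_when_both_candidates_worse(sphere2):
    x = np.array([0.0, 0.0])  # global optimum: nothing can improve on it
    fx = sphere2.objective(x)
    budget = BudgetedProblem(sphere2, 10)
    pos, f, spent, trunc = soft_besiege_dives(
        x, fx, np.array([5.0, 5.0]), 0.4, 1.0, budget,
        np.random.default_rng(0), sphere2.lower, sphere2.upper,
    )
    np.testing.assert_array_equal(pos, x)
    assert f == fx and spent == 2


def test_dive_respects_exhausted_budget(sphere2):
    budget = BudgetedProblem(sphere2, 1)
    budget.evaluate(np.zeros(2))  # exhaust
    x = np.array([1.0, 1.0])
    pos, f, spent, trunc = soft_besiege_dives(
        x, 2.0, np.zeros(2), 0.6, 1.0, budget, np.random.default_rng(0),
        sphere2.lower, sphere2.upper,
    )
    np.testing.assert_array_equal(pos, x)
    assert spent == 0 and trunc


# -- full runs ----------------------------------------------------------------

def test_run_hho_trajectory_monotone_and_budget_conserved(sphere10):
    rec = run_hho(sphere10, 20, 5000, 7)
    fits = [f for _, f in rec.trajectory]
    assert all(b <= a for a, b in zip(fits, fits[1:]))
    assert rec.evaluations <= 5000
    assert rec.ffes_used == rec.evaluations == 5000


def test_run_hho_budget_equal_population_returns_init_best(sphere10):
    rec = run_hho(sphere10, 20, 21, 3)
    assert rec.evaluations == 21
    # one partial iteration at most; best is finite and recorded
    assert np.isfinite(rec.best_fitness)


def test_run_hho_positions_stay_in_box():
    problem = make_builtin("rastrigin", 5)
    rec = run_hho(problem, 10, 1000, 11)
    assert np.all(rec.best_position >= problem.lower)
    assert np.all(rec.best_position <= problem.upper)


def test_run_hho_beats_random_search_on_rastrigin():
    problem = make_builtin("rastrigin", 10)
    hho_finals, rs_finals = [], []
    for seed in range(10):
        hho_finals.append(run_hho(problem, 50, 10000, seed).best_fitness)
        rs_finals.append(random_search(problem, 10000, seed).best_fitness)
    assert np.median(hho_finals) < np.median(rs_finals)


def test_run_hho_per_iteration_accounting_charges_n_per_iteration(sphere10):
    n, max_ffes = 20, 1000
    rec = run_hho(sphere10, n, max_ffes, 5, accounting="per_iteration")
    assert (rec.ffes_used - n) % n == 0
    assert rec.iterations == (rec.ffes_used - n) // n
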