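"""Closed-form selection, critical-age and accumulation results.

Closed forms are checked against independent quadrature, lattice-search and
root-bracketing oracles (tests/oracles.py), and the model's qualitative
limits (semelparity under continuous expression ages, halting under a
grained age grid) are asserted directly.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import (
    critical_age_grid,
    equilibrium_upper_bisect,
    lrs_quadrature,
    selection_quadrature,
)
from senevo.analytic import (
    critical_age,
    equilibrium_interval,
    grained_accumulation,
    iterate_accumulation,
    lifetime_reproductive_success,
    reproductive_success,
    selection_coefficient,
    stationary_fecundity,
)
from senevo.params import LifeHistory, ModelParams


# ---------------------------------------------------------------------------
# stationary fecundity and k(t)


@pytest.mark.parametrize("mu,X", [(0.2, 3.0), (0.46, 5.0), (1.5, 0.7), (0.05, 40.0)])
def test_stationary_fecundity_normalizes_lrs(mu, X):
    """F is pinned so the lifetime reproductive success integrates to one."""
    F = stationary_fecundity(mu, X)
    assert F > mu
    assert lrs_quadrature(mu, X) == pytest.approx(1.0, abs=1e-10)


def test_stationary_fecundity_infinite_X_equals_mu():
    assert stationary_fecundity(0.2, math.inf) == pytest.approx(0.2)


def test_stationary_fecundity_domain_errors():
    with pytest.raises(ValueError):
        stationary_fecundity(0.0, 5.0)
    with pytest.raises(ValueError):
        stationary_fecundity(0.2, 0.0)


def test_reproductive_success_shape():
    lh = LifeHistory(X=5.0, mu=0.46)
    assert reproductive_success(0.0, lh) == pytest.approx(lh.F)
    assert reproductive_success(1 / 0.46, lh) == pytest.approx(lh.F / math.e)
    assert reproductive_success(5.1, lh) == 0.0
    t = np.linspace(0, 5, 50)
    k = reproductive_success(t, lh)
    assert np.all(np.diff(k) < 0)  # strictly decreasing on [0, X]
    with pytest.raises(ValueError):
        reproductive_success(-0.1, lh)


# ---------------------------------------------------------------------------
# mutant LRS and selection coefficient


def test_mutant_lrs_matches_quadrature_and_linearity():
    lh = LifeHistory(X=5.0, mu=0.46)
    assert lifetime_reproductive_success(lh, 1.0, 5.0) == pytest.approx(1.0)
    assert lifetime_reproductive_success(lh, 2.0, 5.0) == pytest.approx(2.0)
    assert lifetime_reproductive_success(lh, 3.7, 0.0) == 0.0
    got = lifetime_reproductive_success(lh, 1.3, 2.2)
    assert got == pytest.approx(lrs_quadrature(0.46, 5.0, alpha=1.3, x=2.2), abs=1e-10)
    with pytest.raises(ValueError):
        lifetime_reproductive_success(lh, 1.0, 5.5)


@pytest.mark.parametrize("alpha", [0.7, 1.0, 2.0])
def test_selection_coefficient_range_and_monotonicity(alpha):
    """s spans [-1, alpha-1], strictly increasing in the lethality age."""
    p = ModelParams(Ne=10, mu=0.46, alpha=alpha)
    X = 5.0
    assert selection_coefficient(0.0, X, p) == pytest.approx(-1.0)
    assert selection_coefficient(X, X, p) == pytest.approx(alpha - 1.0)
    x = np.linspace(0, X, 200)
    s = selection_coefficient(x, X, p)
    assert np.all(np.diff(s) > 0)


def test_selection_coefficient_agrees_with_quadrature():
    p = ModelParams(Ne=50, mu=0.3, alpha=1.4, x_min=0.8)
    for x in (0.8, 1.5, 3.3, 6.0):
        assert selection_coefficient(x, 6.0, p) == pytest.approx(
            selection_quadrature(x, 6.0, p), abs=1e-10
        )


def test_selection_coefficient_domain_error():
    p = ModelParams(Ne=10, mu=0.46)
    with pytest.raises(ValueError):
        selection_coefficient(5.5, 5.0, p)


# ---------------------------------------------------------------------------
# critical age


def test_critical_age_nonsenescent_limit_is_log_ne_over_mu():
    p = ModelParams(Ne=10, mu=0.46)
    assert critical_age(math.inf, p) == pytest.approx(math.log(10) / 0.46, rel=1e-14)


def test_critical_age_vanishes_with_maximum_age():
    p = ModelParams(Ne=1e3, mu=0.2)
    assert critical_age(1e-8, p) < 1e-6


def test_critical_age_matches_grid_oracle_spot_checks():
    for p, X in [
        (ModelParams(Ne=10, mu=0.46), 5.0),
        (ModelParams(Ne=1e3, mu=0.2), math.inf),
        (ModelParams(Ne=100, mu=0.8, alpha=1.5), 7.0),
        (ModelParams(Ne=40, mu=0.3, alpha=0.99), 12.0),
    ]:
        closed = critical_age(X, p)
        grid = critical_age_grid(X, p)
        assert abs(closed - grid) <= 1e-6 + 1e-9


def test_critical_age_translates_with_age_at_first_reproduction():
    """s depends only on ages relative to x_min, so x_star shifts with it."""
    base = ModelParams(Ne=200, mu=0.35, alpha=1.1)
    shifted = ModelParams(Ne=200, mu=0.35, alpha=1.1, x_min=2.5)
    assert critical_age(8.0 + 2.5, shifted) == pytest.approx(
        critical_age(8.0, base) + 2.5, rel=1e-12
    )
    grid = critical_age_grid(10.5, shifted)
    assert abs(critical_age(10.5, shifted) - grid) <= 1e-6 + 1e-9


def test_critical_age_none_when_fecundity_cost_blocks_invasion():
    # alpha <= (Ne-1)/Ne makes s(X) = alpha-1 <= -1/Ne at every age
    p = ModelParams(Ne=10, mu=0.46, alpha=0.85)
    assert critical_age(5.0, p) is None
    assert critical_age(math.inf, p) is None


def test_critical_age_selection_threshold_zero():
    # threshold 0: age above which a fecundity-enhancing mutant is favored
    p = ModelParams(Ne=10, mu=0.46, alpha=1.5)
    x0 = critical_age(math.inf, p, threshold=0.0)
    assert selection_coefficient(x0, math.inf, p) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        critical_age(5.0, p, threshold=-1.0)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    Ne=st.floats(1.0001, 1e6),
    mu=st.floats(1e-3, 2.0),
    alpha=st.floats(0.5, 2.0),
    X=st.floats(1e-3, 50.0),
)
def test_critical_age_below_current_maximum(Ne, mu, alpha, X):
    """Whenever a critical age exists it lies strictly inside [x_min, X)."""
    p = ModelParams(Ne=Ne, mu=mu, alpha=alpha)
    xs = critical_age(X, p)
    if xs is not None:
        assert 0.0 <= xs < X
        assert selection_coefficient(xs, X, p) == pytest.approx(
            -1.0 / Ne, abs=1e-9
        )


# ---------------------------------------------------------------------------
# sequential fixation, continuous ages


def test_iteration_collapses_to_age_of_first_reproduction():
    p = ModelParams(Ne=10, mu=0.46)
    traj = iterate_accumulation(p, X0=math.inf, max_steps=10000, stop_tol=1e-6)
    ages = traj.ages()
    assert ages[1] == pytest.approx(math.log(10) / 0.46)
    assert np.all(np.diff(ages[1:]) < 0)
    assert traj.terminated_reason == "reached_x_min"
    assert traj.final_age < 1e-6


def test_iteration_replays_critical_age_step_by_step():
    p = ModelParams(Ne=1e3, mu=0.2)
    traj = iterate_accumulation(p, X0=math.inf, max_steps=50)
    for (n0, X0), (n1, X1) in zip(traj.steps, traj.steps[1:]):
        assert n1 == n0 + 1
        assert X1 == pytest.approx(critical_age(X0, p), rel=1e-14)
        grid = critical_age_grid(X0, p)
        assert abs(X1 - grid) <= 1e-6 + 1e-9


def test_iteration_single_step_when_no_age_invadable():
    p = ModelParams(Ne=10, mu=0.46, alpha=0.5)
    traj = iterate_accumulation(p, X0=20.0)
    assert traj.steps == ((0, 20.0),)
    assert traj.terminated_reason == "no_invadable_age"


def test_iteration_respects_x_min_floor():
    p = ModelParams(Ne=50, mu=0.4, x_min=1.5)
    traj = iterate_accumulation(p, X0=math.inf, max_steps=10000, stop_tol=1e-5)
    assert traj.terminated_reason == "reached_x_min"
    assert traj.final_age == pytest.approx(1.5, abs=1e-4)
    assert np.all(traj.ages()[1:] > 1.5 - 1e-12)


def test_iteration_domain_errors():
    p = ModelParams(Ne=10, mu=0.46)
    with pytest.raises(ValueError):
        iterate_accumulation(p, X0=-1.0)
    with pytest.raises(ValueError):
        iterate_accumulation(p, X0=5.0, max_steps=0)


# ---------------------------------------------------------------------------
# grained ages: halting and the equilibrium interval


def test_grained_accumulation_halts_above_zero_inside_interval():
    p = ModelParams(Ne=10, mu=0.46, delta=2.0)
    traj = grained_accumulation(p, X0=math.inf)
    assert traj.terminated_reason == "no_invadable_age"
    assert traj.final_age == pytest.approx(6.0)  # grid age, > 0
    iv = equilibrium_interval(p)
    assert traj.final_age in iv
    # every later age is a grid point and each step is the smallest
    # invadable grid age below its predecessor
    for (_, Xp), (_, Xn) in zip(traj.steps, traj.steps[1:]):
        assert Xn / p.delta == pytest.approx(round(Xn / p.delta))
        assert critical_age(Xp, p) < Xn < Xp


@pytest.mark.parametrize("delta", [0.5, 1.0, 2.0])
def test_grained_final_age_always_lands_in_equilibrium_interval(delta):
    p = ModelParams(Ne=1e3, mu=0.2, delta=delta)
    traj = grained_accumulation(p, X0=math.inf)
    assert traj.final_age in equilibrium_interval(p)


def test_grained_halts_immediately_when_grain_exceeds_window():
    # no grid age inside (x_star, X0): the maximum age at death is stuck
    p = ModelParams(Ne=10, mu=0.46, delta=6.0)
    traj = grained_accumulation(p, X0=6.0)
    assert traj.steps == ((0, 6.0),)
    assert traj.terminated_reason == "no_invadable_age"


def test_equilibrium_interval_closed_form_properties():
    p = ModelParams(Ne=1e3, mu=0.2, delta=1.0)
    iv = equilibrium_interval(p)
    assert iv.width == pytest.approx(p.delta, abs=1e-12)
    # lower bound is the critical age evaluated at the upper bound
    assert critical_age(iv.upper, p) == pytest.approx(iv.lower, rel=1e-12)
    # upper bound solves X - x_star(X) = delta (independent bracketing)
    assert iv.upper == pytest.approx(equilibrium_upper_bisect(p), abs=1e-10)


def test_equilibrium_interval_degenerates_as_grain_vanishes():
    # at alpha = 1 the upper bound behaves as ~ Ne*delta for small delta
    for delta in (1e-4, 1e-7):
        iv = equilibrium_interval(ModelParams(Ne=1e3, mu=0.2, delta=delta))
        assert 0.0 <= iv.lower <= iv.upper <= 2 * 1e3 * delta


def test_equilibrium_interval_requires_positive_delta_and_invadability():
    with pytest.raises(ValueError):
        equilibrium_interval(ModelParams(Ne=10, mu=0.2, delta=0.0))
    assert equilibrium_interval(ModelParams(Ne=10, mu=0.2, alpha=0.5, delta=1.0)) is None


def test_equilibrium_upper_monotone_on_parameter_lattice():
    """Evolved maximum age at death falls with lower Ne, higher mu, higher alpha."""
    Nes = [30.0, 300.0, 3000.0]
    mus = [0.1, 0.3, 0.9]
    alphas = [1.0, 1.2, 1.6]  # all above the invadability bound (Ne-1)/Ne
    upper = {
        (Ne, mu, a): equilibrium_interval(
            ModelParams(Ne=Ne, mu=mu, alpha=a, delta=1.0)
        ).upper
        for Ne in Nes
        for mu in mus
        for a in alphas
    }
    for mu in mus:
        for a in alphas:
            assert upper[(30.0, mu, a)] < upper[(300.0, mu, a)] < upper[(3000.0, mu, a)]
    for Ne in Nes:
        for a in alphas:
            assert upper[(Ne, 0.1, a)] > upper[(Ne, 0.3, a)] > upper[(Ne, 0.9, a)]
    for Ne in Nes:
        for mu in mus:
            assert upper[(Ne, mu, 1.0)] > upper[(Ne, mu, 1.2)] > upper[(Ne, mu, 1.6)]
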