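"""Closed-form selection, critical-age and sequential-fixation results.

A density-regulated stationary population has lifetime reproductive success
(LRS) equal to one.  With age-independent extrinsic mortality ``mu`` and
constant fecundity ``F``, the age-specific reproductive success is
``k(t) = F*exp(-mu*t)`` on ``[x_min, X]`` and stationarity forces
``F = mu / (exp(-mu*x_min) - exp(-mu*X))``.

A mutant carrying a dominant mutation lethal at age ``x`` (and a fecundity
multiplier ``alpha``) has ``LRS_mut = alpha * integral(k, x_min, x)``, so its
selection coefficient is ``s(x) = LRS_mut - 1``, strictly increasing from
``-1`` at ``x = x_min`` to ``alpha - 1`` at ``x = X``.  Such a mutation can
fix by drift whenever ``s(x) > -1/Ne``; the age at which ``s`` crosses the
drift barrier is the *critical age* ``x_star``.  Because every fixation
resets the stationary fecundity upward, the critical age itself shrinks
after each fixation, and iterating the invasion argument collapses the
maximum age at death toward the age at first reproduction — unless the ages
at which mutational effects can occur are restricted to a grid of grain
``delta``, in which case the collapse halts inside a closed-form interval
of width ``delta``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .params import LifeHistory, ModelParams, _stationary_fecundity

__all__ = [
    "AccumulationTrajectory",
    "EquilibriumInterval",
    "stationary_fecundity",
    "reproductive_success",
    "lifetime_reproductive_success",
    "selection_coefficient",
    "critical_age",
    "iterate_accumulation",
    "grained_accumulation",
    "equilibrium_interval",
]


# ---------------------------------------------------------------------------
# Result containers


@dataclass(frozen=True)
class AccumulationTrajectory:
    """Ordered record of maximum ages at death during sequential fixation."""

    params: ModelParams
    steps: tuple[tuple[int, float], ...]
    terminated_reason: str  # reached_x_min | no_invadable_age | max_steps

    def ages(self) -> np.ndarray:
        return np.array([x for _, x in self.steps], dtype=float)

    @property
    def final_age(self) -> float:
        return self.steps[-1][1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "X"])


@dataclass(frozen=True)
class EquilibriumInterval:
    """Bracket for the evolved maximum age at death under grain ``delta``.

    ``upper`` is the maximum age at death at which the critical age sits
    exactly one grain below (``X - x_star(X) = delta``); ``lower`` is the
    critical age evaluated at ``upper``, so ``upper - lower == delta``.
    """

    lower: float
    upper: float

    def __contains__(self, age: float) -> bool:
        return self.lower <= age <= self.upper

    @property
    def width(self) -> float:
        return self.upper - self.lower


# ---------------------------------------------------------------------------
# Stationary demography


def stationary_fecundity(mu: float, X: float, x_min: float = 0.0) -> float:
    """Fecundity of the stationary population with maximum age at death ``X``.

    Solves ``LRS = integral(F*exp(-mu*t), x_min, X) = 1``; finite ``X`` gives
    ``F > mu`` — recruitment compensates the deaths caused by the fixed
    lethal — while ``X = inf`` (nonsenescent) gives ``F = mu`` at
    ``x_min = 0``.
    """
    if not mu > 0:
        raise ValueError(f"mu must be > 0, got {mu}")
    if not X > x_min:
        raise ValueError(f"X must exceed x_min, got X={X}, x_min={x_min}")
    return _stationary_fecundity(mu, X, x_min)


def reproductive_success(t, lh: LifeHistory):
    """Age-specific reproductive success ``k(t) = F*exp(-mu*t)``, 0 past X.

    ``t`` may be a scalar or array of ages; negative ages are rejected.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("age t must be non-negative")
    k = np.where(t_arr <= lh.X, lh.F * np.exp(-lh.mu * t_arr), 0.0)
    return float(k) if np.isscalar(t) or t_arr.ndim == 0 else k


def lifetime_reproductive_success(lh: LifeHistory, alpha: float, x: float) -> float:
    """LRS of a mutant lethal at age ``x`` with fecundity ``alpha*F``.

    Closed form of ``alpha * integral(k, x_min, x)``; equals 1 at
    ``alpha = 1, x = X`` by stationarity.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    if not lh.x_min <= x <= lh.X:
        raise ValueError(f"x={x} outside [{lh.x_min}, {lh.X}]")
    return alpha * lh.F / lh.mu * (math.exp(-lh.mu * lh.x_min) - math.exp(-lh.mu * x))


def selection_coefficient(x, X: float, params: ModelParams):
    """Selection coefficient ``s(x)`` on a mutation lethal at age ``x``.

    ``s(x) = alpha*(1 - exp(-mu*(x - x_min))) / (1 - exp(-mu*(X - x_min))) - 1``
    (the ``exp(-mu*x_min)`` survival factor cancels between mutant and
    wild-type LRS).  Strictly increasing on ``[x_min, X]`` with range
    ``[-1, alpha - 1]``; ``X`` may be infinite.
    """
    mu, alpha, x_min = params.mu, params.alpha, params.x_min
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < x_min) or np.any(x_arr > X):
        raise ValueError(f"x outside [{x_min}, {X}]")
    denom = 1.0 if math.isinf(X) else -math.expm1(-mu * (X - x_min))
    s = alpha * (-np.expm1(-mu * (x_arr - x_min))) / denom - 1.0
    return float(s) if np.isscalar(x) or x_arr.ndim == 0 else s


def critical_age(
    X: float,
    params: ModelParams,
    threshold: Optional[float] = None,
) -> Optional[float]:
    """Age above which a lethal mutation crosses the invasion threshold.

    Returns the unique ``x_star`` in ``[x_min, X)`` with
    ``s(x_star) = threshold`` (default: the drift barrier ``-1/Ne``), or
    ``None`` when ``s(X) = alpha - 1 <= threshold`` so that no expression
    age allows invasion.  With ``threshold = 0`` this is instead the age
    above which a fecundity-enhancing pleiotropic mutant invades by
    selection.

    At ``x_min = 0`` and ``threshold = -1/Ne`` the closed form is
    ``x_star = (1/mu) * ln(alpha*Ne / (Ne*(alpha-1) + 1 + exp(-mu*X)*(Ne-1)))``,
    which tends to ``ln(Ne)/mu`` as ``X -> inf`` (``alpha = 1``) and to 0 as
    ``X -> 0+``.
    """
    if threshold is None:
        threshold = params.drift_threshold
    if threshold <= -1.0:
        raise ValueError(f"threshold must exceed -1, got {threshold}")
    x_min, mu, alpha = params.x_min, params.mu, params.alpha
    if not (X > x_min):
        raise ValueError(f"X must exceed x_min={x_min}, got {X}")
    if alpha - 1.0 <= threshold or alpha == 0.0:
        return None  # s(x) <= threshold at every age: cannot invade
    # Work in ages relative to x_min; the exp(-mu*x_min) factor cancels in s.
    span = 1.0 if math.isinf(X) else -math.expm1(-mu * (X - x_min))
    w = (1.0 + threshold) * span / alpha  # = exp(-mu*(x_star - x_min)) deficit
    return x_min - math.log1p(-w) / mu


def iterate_accumulation(
    params: ModelParams,
    X0: float = math.inf,
    max_steps: int = 1000,
    stop_tol: float = 1e-6,
    epsilon: float = 0.0,
) -> AccumulationTrajectory:
    """Sequential fixation with each mutation lethal exactly at the critical age.

    Iterates ``X_{n+1} = x_star(X_n) + epsilon`` from ``X0`` until the
    maximum age at death comes within ``stop_tol`` of the age at first
    reproduction, no mutation can invade, or ``max_steps`` is reached.
    With ``alpha = 1`` the trajectory decreases strictly toward ``x_min``
    (evolution toward semelparity).
    """
    if not X0 > params.x_min:
        raise ValueError(f"X0 must exceed x_min={params.x_min}, got {X0}")
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    if not stop_tol > 0:
        raise ValueError("stop_tol must be > 0")
    steps = [(0, X0)]
    reason = "max_steps"
    X = X0
    for n in range(1, max_steps + 1):
        if X - params.x_min < stop_tol:
            reason = "reached_x_min"
            break
        x_star = critical_age(X, params)
        if x_star is None:
            reason = "no_invadable_age"
            break
        X_next = x_star + epsilon
        if not X_next < X:
            reason = "no_invadable_age"
            break
        steps.append((n, X_next))
        X = X_next
    else:
        reason = "max_steps"
    if X - params.x_min < stop_tol:
        reason = "reached_x_min"
    return AccumulationTrajectory(params, tuple(steps), reason)


def grained_accumulation(
    params: ModelParams,
    X0: float = math.inf,
    max_steps: int = 1000,
) -> AccumulationTrajectory:
    """Sequential fixation when lethal effects occur only on an age grid.

    Expression ages are restricted to ``x_min + j*delta`` (j = 1, 2, ...).
    Each step fixes the mutation with the *earliest* invadable grid age:
    the smallest grid age strictly above the current critical age and
    strictly below the current maximum age at death.  The iteration halts
    when no grid age lies in that window; the final age then sits inside
    ``equilibrium_interval(params)``.
    """
    if not params.delta > 0:
        raise ValueError("grained accumulation requires delta > 0")
    if not X0 > params.x_min:
        raise ValueError(f"X0 must exceed x_min={params.x_min}, got {X0}")
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    delta, x_min = params.delta, params.x_min
    steps = [(0, X0)]
    reason = "max_steps"
    X = X0
    for n in range(1, max_steps + 1):
        x_star = critical_age(X, params)
        if x_star is None:
            reason = "no_invadable_age"
            break
        # smallest grid age x_min + j*delta strictly inside (x_star, X)
        j = math.floor((x_star - x_min) / delta) + 1
        while x_min + j * delta <= x_star:  # guard fp boundary
            j += 1
        X_next = x_min + j * delta
        if not X_next < X:
            reason = "no_invadable_age"
            break
        steps.append((n, X_next))
        X = X_next
    return AccumulationTrajectory(params, tuple(steps), reason)


def equilibrium_interval(params: ModelParams) -> Optional[EquilibriumInterval]:
    """Closed-form bracket for the evolved maximum age at death (grain ``delta``).

    The last mutation able to invade has its lethal effect within
    ``[X_dagger - delta, X_dagger]`` where ``X_dagger`` solves
    ``X - x_star(X) = delta``:

    ``upper = x_min + (1/mu) * ln((Ne*(alpha*e^{mu*delta} - 1) + 1) / (Ne*(alpha-1) + 1))``
    ``lower = upper - delta``

    Returns ``None`` when ``alpha <= (Ne-1)/Ne`` (no age is invadable, so no
    equilibrium of accumulation exists); raises on ``delta <= 0``.
    """
    Ne, mu, alpha, delta = params.Ne, params.mu, params.alpha, params.delta
    if not delta > 0:
        raise ValueError("equilibrium_interval requires delta > 0")
    if alpha - 1.0 <= params.drift_threshold:
        return None
    denom = Ne * (alpha - 1.0) + 1.0
    upper = params.x_min + math.log((Ne * (alpha * math.exp(mu * delta) - 1.0) + 1.0) / denom) / mu
    return EquilibriumInterval(lower=upper - delta, upper=upper)
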