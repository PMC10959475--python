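"""Parameter bundles for the analytic senescence model.

The model describes a density-regulated, stationary population in which
age-dependent dominant lethal mutations fix by genetic drift whenever the
selection purging them is weaker than the drift barrier ``-1/Ne``.  All
analytic results are parameterized by the effective population size ``Ne``,
the age-independent extrinsic adult mortality rate ``mu``, the pleiotropy
multiplier ``alpha`` scaling mutant fecundity, the age at first reproduction
``x_min``, and the grain ``delta`` of the ages at which mutational effects
can occur (``delta = 0`` encodes a continuum of expression ages).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the analytic mutation-accumulation model.

    Parameters
    ----------
    Ne : float
        Effective population size; must exceed 1 so the drift barrier
        ``-1/Ne`` lies strictly inside ``(-1, 0)``.
    mu : float
        Extrinsic adult mortality rate per unit age, independent of age.
    alpha : float
        Fecundity multiplier of mutants (``alpha = 1``: no pleiotropy;
        ``alpha > 1``: fecundity benefit; ``alpha < 1``: fecundity cost).
    x_min : float
        Age at first reproduction (default 0).
    delta : float
        Grain of the age dependence of mutational effects: lethal effects
        can occur only at ages ``x_min + j*delta``; 0 means any age.
    """

    Ne: float
    mu: float
    alpha: float = 1.0
    x_min: float = 0.0
    delta: float = 0.0

    def __post_init__(self) -> None:
        if not self.Ne > 1:
            raise ValueError(f"Ne must be > 1, got {self.Ne}")
        if not self.mu > 0:
            raise ValueError(f"mu must be > 0, got {self.mu}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.x_min < 0:
            raise ValueError(f"x_min must be >= 0, got {self.x_min}")
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta}")

    @property
    def drift_threshold(self) -> float:
        """The drift barrier ``-1/Ne``."""
        return -1.0 / self.Ne


@dataclass(frozen=True)
class LifeHistory:
    """A stationary life history with maximum age at death ``X``.

    Survival to age ``t`` is ``exp(-mu*t)`` and fecundity ``F`` is constant
    over ``[x_min, X]``.  Stationarity (lifetime reproductive success equal
    to one) pins the fecundity at ``F = mu / (exp(-mu*x_min) - exp(-mu*X))``,
    which reduces to ``F = mu`` for a nonsenescent population
    (``X`` infinite, ``x_min = 0``).
    """

    X: float
    mu: float
    x_min: float = 0.0
    F: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError(f"mu must be > 0, got {self.mu}")
        if self.x_min < 0:
            raise ValueError(f"x_min must be >= 0, got {self.x_min}")
        if not self.X > self.x_min:
            raise ValueError(f"X must exceed x_min, got X={self.X}, x_min={self.x_min}")
        object.__setattr__(self, "F", _stationary_fecundity(self.mu, self.X, self.x_min))

    @property
    def finite(self) -> bool:
        return math.isfinite(self.X)


def _stationary_fecundity(mu: float, X: float, x_min: float = 0.0) -> float:
    """Fecundity forcing LRS = 1 for survival exp(-mu*t) on [x_min, X]."""
    if math.isinf(X):
        return mu * math.exp(mu * x_min)
    return mu / (math.exp(-mu * x_min) - math.exp(-mu * X))
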