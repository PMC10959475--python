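"""Independent numerical oracles used to cross-check the closed forms.

These deliberately avoid the package's closed-form code paths: lifetime
reproductive success is integrated by adaptive quadrature, the critical age
is located by exhaustive search over a fine age lattice (binary search
exploits only the monotonicity of the selection coefficient, which the
quadrature oracle verifies separately), and the equilibrium upper bound is
found by root bracketing on its defining equation.
"""

from __future__ import annotations

import math

from scipy.integrate import quad
from scipy.optimize import brentq

from senevo.analytic import critical_age, selection_coefficient
from senevo.params import ModelParams


def lrs_quadrature(mu: float, X: float, x_min: float = 0.0, alpha: float = 1.0,
                   x: float | None = None) -> float:
    """alpha * integral of F*exp(-mu*t) over [x_min, x] by quadrature."""
    if x is None:
        x = X
    if math.isinf(X):
        F = mu * math.exp(mu * x_min)
        hi = min(x, x_min + 700.0 / mu)  # integrand is zero beyond this
    else:
        F = mu / (math.exp(-mu * x_min) - math.exp(-mu * X))
        hi = x
    val, err = quad(lambda t: F * math.exp(-mu * t), x_min, hi, epsabs=1e-13,
                    limit=200)
    return alpha * val


def selection_quadrature(x: float, X: float, params: ModelParams) -> float:
    """s(x) = LRS_mut - 1 with the mutant LRS integrated numerically."""
    return lrs_quadrature(params.mu, X, params.x_min, params.alpha, x) - 1.0


def critical_age_grid(X: float, params: ModelParams, grid: float = 1e-6,
                      threshold: float | None = None) -> float | None:
    """Smallest lattice age x_min + k*grid with s(x) > threshold.

    Binary search over the lattice index (s is strictly increasing in x);
    returns None when even the topmost lattice age at or below X fails the
    threshold.
    """
    if threshold is None:
        threshold = params.drift_threshold
    x_min = params.x_min
    span = (X - x_min) if math.isfinite(X) else 60.0 / params.mu + 60.0
    K = int(math.floor(span / grid))

    def s_at(k: int) -> float:
        return selection_coefficient(x_min + k * grid, X, params)

    if not s_at(K) > threshold:
        return None
    lo, hi = 0, K  # invariant: s_at(hi) > threshold
    if s_at(0) > threshold:
        return x_min
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if s_at(mid) > threshold:
            hi = mid
        else:
            lo = mid
    return x_min + hi * grid


def equilibrium_upper_bisect(params: ModelParams) -> float:
    """Root of X - x_star(X) = delta by bracketing (defines the upper bound)."""

    def f(X: float) -> float:
        xs = critical_age(X, params)
        if xs is None:
            raise ValueError("no critical age inside the bracket")
        return (X - xs) - params.delta

    lo = params.x_min + 1e-9
    hi = params.x_min + 10.0 * (params.delta + 1.0 / params.mu)
    while f(hi) < 0:
        hi = params.x_min + 2 * (hi - params.x_min)
    return brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16)
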