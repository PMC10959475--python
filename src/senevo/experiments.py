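"""Parameter sweeps and replicate batteries.

Turns the analytic module's trajectories and equilibrium intervals into
long-format tables (one-factor-at-a-time variations around the baseline
Ne = 1e3, mu = 0.2, alpha = 1), and orchestrates batteries of
individual-based replicates over the model's qualitative regimes:
continuous decline of the maximum age at death under a fine expression-age
grid, halting under a coarse grid, census collapse under capped
recruitment, and persistence of the decline under reverse mutation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import analytic
from .ibm import SimConfig, run
from .params import ModelParams

__all__ = [
    "SweepSpec",
    "figure1b_table",
    "figure2c_table",
    "ibm_battery",
    "default_trajectory_sweep",
    "default_equilibrium_sweep",
    "default_battery",
]


@dataclass(frozen=True)
class SweepSpec:
    """A grid of parameter cells plus the operation applied per cell.

    ``operation`` is one of ``"trajectory"``, ``"equilibrium"`` (cells are
    ``ModelParams``) or ``"ibm"`` (cells are ``(label, SimConfig)`` pairs).
    For stochastic cells, replicate ``r`` of a cell runs with seed
    ``base_seed + r`` offset from the cell's own seed.
    """

    operation: str
    cells: tuple
    replicates: int = 1
    base_seed: int = 0
    X0: float = math.inf
    max_steps: int = 500

    def __post_init__(self) -> None:
        if self.operation not in ("trajectory", "equilibrium", "ibm"):
            raise ValueError(f"unknown operation {self.operation!r}")
        if not self.cells:
            raise ValueError("sweep grid must be non-empty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def default_trajectory_sweep(max_steps: int = 500) -> SweepSpec:
    """Baseline Ne=1e3, mu=0.2, alpha=1 plus one-factor variations."""
    cells = (
        ModelParams(Ne=1e3, mu=0.2, alpha=1.0),
        ModelParams(Ne=1e2, mu=0.2, alpha=1.0),  # lower Ne
        ModelParams(Ne=1e3, mu=0.4, alpha=1.0),  # higher mu
        ModelParams(Ne=1e3, mu=0.2, alpha=1.2),  # stronger pleiotropy
    )
    return SweepSpec("trajectory", cells, max_steps=max_steps)


def default_equilibrium_sweep(
    deltas: Sequence[float] = (0.25, 0.5, 1.0, 2.0, 4.0),
) -> SweepSpec:
    """Equilibrium intervals as a function of the grain delta."""
    cells = []
    for Ne, mu, alpha in [(1e3, 0.2, 1.0), (1e2, 0.2, 1.0), (1e3, 0.4, 1.0), (1e3, 0.2, 1.2)]:
        for d in deltas:
            cells.append(ModelParams(Ne=Ne, mu=mu, alpha=alpha, delta=d))
    return SweepSpec("equilibrium", tuple(cells))


def figure1b_table(spec: SweepSpec) -> pd.DataFrame:
    """Sequential-fixation trajectories, long format.

    One row per (parameter cell, iteration step); the ``X`` column is the
    maximum age at death, strictly decreasing within each cell and
    converging to ``x_min`` whenever invasion never stalls.  Cells with
    ``delta > 0`` iterate on the grained age grid.
    """
    if spec.operation != "trajectory":
        raise ValueError("figure1b_table requires a trajectory sweep")
    rows = []
    for p in spec.cells:
        if not isinstance(p, ModelParams):
            raise ValueError("trajectory cells must be ModelParams")
        if p.delta > 0:
            traj = analytic.grained_accumulation(p, X0=spec.X0, max_steps=spec.max_steps)
        else:
            traj = analytic.iterate_accumulation(p, X0=spec.X0, max_steps=spec.max_steps)
        for n, X in traj.steps:
            rows.append(
                dict(
                    Ne=p.Ne, mu=p.mu, alpha=p.alpha, delta=p.delta,
                    step=n, X=X, terminated=traj.terminated_reason,
                )
            )
    return pd.DataFrame(rows)


def figure2c_table(spec: SweepSpec) -> pd.DataFrame:
    """Equilibrium maximum-age-at-death brackets per (Ne, mu, alpha, delta).

    ``upper`` increases with ``delta`` within each (Ne, mu, alpha) group: a
    coarser grain of mutational age dependence halts the accumulation at a
    higher maximum age at death.
    """
    if spec.operation != "equilibrium":
        raise ValueError("figure2c_table requires an equilibrium sweep")
    rows = []
    for p in spec.cells:
        if not isinstance(p, ModelParams):
            raise ValueError("equilibrium cells must be ModelParams")
        if not p.delta > 0:
            raise ValueError("equilibrium cells require delta > 0")
        iv = analytic.equilibrium_interval(p)
        rows.append(
            dict(
                Ne=p.Ne, mu=p.mu, alpha=p.alpha, delta=p.delta,
                lower=math.nan if iv is None else iv.lower,
                upper=math.nan if iv is None else iv.upper,
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# IBM battery


def default_battery(
    N: int = 300,
    replicates: int = 20,
    base_seed: int = 0,
) -> SweepSpec:
    """The four qualitative regimes of the individual-based model.

    All cells share mu = 0.46 (the analytic illustrations' mortality
    rate), a unit time step and a mutation-rich regime (U = 0.05,
    expression ages up to ~3x the nonsenescent critical age ln(N)/mu).

    - ``fine``: expression-age grain equal to the step length — the
      maximum age at death ratchets steadily downward.
    - ``coarse``: grain of 4 age units — the ratchet halts at the grained
      equilibrium.
    - ``capped``: fine grain at a half-unit step plus a recruitment cap
      F_max = 0.416.  Viability requires the per-step birth allowance
      F_max*dt to exceed the stationary per-step death fraction, which
      rises from mu_step ~ 0.2054 for a nonsenescent population to ~0.2088
      once the maximum age at death falls to 9 — below the cap's allowance
      of 0.2080 — so the census is stable while the population is
      long-lived and collapses as the ratchet approaches its halting age.
    - ``reverse``: fine grain plus per-allele reversion at rate 1e-4 —
      population-scaled reversion 2*N*r << 1, a biologically small rate —
      and the decline persists.
    """
    base = SimConfig(
        N=N, mu=0.46, dt=1.0, U=0.05, age_grid_delta=1.0, max_expr_age=36.0,
        effect="lethal", T_max=8000, record_every=10,
    )
    cells = (
        ("fine", base),
        ("coarse", replace(base, age_grid_delta=4.0)),
        ("capped", replace(base, dt=0.5, age_grid_delta=0.5, F_max=0.416,
                           T_max=24000)),
        ("reverse", replace(base, reverse_rate=1e-4)),
    )
    return SweepSpec("ibm", cells, replicates=replicates, base_seed=base_seed)


def _decline_slope(times: np.ndarray, fmax: np.ndarray) -> float:
    """Least-squares slope of the fixed-lethal max age over the finite part."""
    finite = np.isfinite(fmax)
    if finite.sum() < 2:
        return math.nan
    t, y = times[finite].astype(float), fmax[finite]
    return float(np.polyfit(t, y, 1)[0])


def _plateau_age(times: np.ndarray, fmax: np.ndarray, tail: float = 0.25) -> float:
    """Final fixed max age if it was constant over the last ``tail`` of the run."""
    if not len(fmax) or not np.isfinite(fmax[-1]):
        return math.nan
    cut = times[-1] - tail * (times[-1] - times[0])
    tail_vals = fmax[times >= cut]
    return float(fmax[-1]) if np.all(tail_vals == fmax[-1]) else math.nan


def ibm_battery(spec: SweepSpec) -> pd.DataFrame:
    """Run replicate batteries of the IBM and summarize each cell.

    Per cell: median decline slope of the fixed-lethal maximum age at
    death, median plateau age (NaN when no plateau was held over the last
    quarter of the run), extinction fraction, median extinction time, and
    the median final maximum age at death.  Deterministic given the seed
    policy (replicate ``r`` uses ``config.seed + base_seed + r``).
    """
    if spec.operation != "ibm":
        raise ValueError("ibm_battery requires an ibm sweep")
    rows = []
    for label, config in spec.cells:
        if not isinstance(config, SimConfig):
            raise ValueError("ibm cells must be (label, SimConfig) pairs")
        records = [
            run(replace(config, seed=config.seed + spec.base_seed + r))
            for r in range(spec.replicates)
        ]
        slopes = [_decline_slope(rec.times, rec.fixed_max_age) for rec in records]
        plateaus = [_plateau_age(rec.times, rec.fixed_max_age) for rec in records]
        finals = [
            rec.fixed_max_age[-1] if len(rec.fixed_max_age) else math.inf
            for rec in records
        ]
        ext = [rec.extinction_time for rec in records]
        n_ext = sum(e is not None for e in ext)
        rows.append(
            dict(
                cell=label,
                replicates=spec.replicates,
                median_decline_slope=float(np.nanmedian(slopes))
                if np.any(np.isfinite(slopes))
                else math.nan,
                median_plateau_age=float(np.nanmedian(plateaus))
                if np.any(np.isfinite(plateaus))
                else math.nan,
                plateau_fraction=float(np.mean(np.isfinite(plateaus))),
                extinction_fraction=n_ext / spec.replicates,
                median_extinction_time=float(
                    np.median([e for e in ext if e is not None])
                )
                if n_ext
                else math.nan,
                median_final_max_age=float(np.median(finals)),
            )
        )
    return pd.DataFrame(rows)


def battery_median_trajectory(
    config: SimConfig, replicates: int, base_seed: int = 0
) -> pd.DataFrame:
    """Replicate-median fixed-lethal max age over time for one cell."""
    records = [
        run(replace(config, seed=config.seed + base_seed + r))
        for r in range(replicates)
    ]
    n = min(len(rec.times) for rec in records)
    times = records[0].times[:n]
    stack = np.vstack([rec.fixed_max_age[:n] for rec in records])
    return pd.DataFrame(
        {"time": times, "median_fixed_max_age": np.median(stack, axis=0)}
    )
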