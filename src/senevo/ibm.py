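"""Individual-based simulator of lethal-mutation accumulation.

Forward-in-time, discrete-step simulation of a well-mixed, density-regulated
diploid population.  Dominant mutations lethal at specific expression ages
(or somatic stages) arise in offspring, drift, and occasionally fix; each
fixation lowers the population's maximum age at death, and recruitment
compensation keeps the census at the target ``N`` — until an optional
recruitment cap ``F_max`` makes full compensation impossible and the census
collapses.  This realizes, with explicit drift, the sequential-fixation
ratchet that the analytic module idealizes.

State is held in flat numpy arrays (one row per living individual, one
genotype column per segregating locus, parallel per-locus attribute
arrays); lost loci are compacted away and, when reverse mutation is
disabled, fixed lethal loci are folded into a scalar "earliest fixed kill
age" so the genotype matrix stays small.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "SimConfig",
    "MutationLocus",
    "PopulationState",
    "SimRecord",
    "init_population",
    "step",
    "run",
    "fixed_lethal_max_age",
    "somatic_advance",
]

_LETHAL, _MORTALITY = 0, 1


@dataclass(frozen=True)
class MutationLocus:
    """A germline mutation with an age- (or stage-) dependent effect.

    ``expression_trigger`` is an age in age units (age-triggered mode) or a
    somatic stage index (somatic mode).  ``effect`` is ``"lethal"`` or
    ``"mortality"`` (the latter adds ``d`` to the per-step death
    probability once triggered).  ``pleiotropy`` multiplies the carrier's
    fecundity weight.
    """

    id: int
    expression_trigger: float
    effect: str = "lethal"
    d: float = 1.0
    pleiotropy: float = 1.0
    origin_time: int = 0

    def __post_init__(self) -> None:
        if self.effect not in ("lethal", "mortality"):
            raise ValueError(f"unknown effect {self.effect!r}")
        if self.effect == "mortality" and not 0 < self.d <= 1:
            raise ValueError(f"mortality increment d must be in (0,1], got {self.d}")
        if self.pleiotropy < 0:
            raise ValueError("pleiotropy must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulation run.

    Parameters
    ----------
    N : int
        Census size target (>= 2); with unlimited recruitment the census is
        exactly N at the end of every step.
    mu : float
        Extrinsic mortality rate per unit age; the per-step death
        probability is ``mu_step = 1 - exp(-mu*dt)``.
    dt : float
        Step length in age units.
    U : float
        Probability that an offspring carries one new mutation.
    age_grid_delta : float
        Grain of newly drawn expression ages (``0`` draws continuous ages;
        the effective grain can never be finer than ``dt`` because ages
        advance in steps of ``dt``).
    max_expr_age : float
        Upper bound of newly drawn expression ages, in age units.
    effect : str
        Effect of new mutations: ``"lethal"`` or ``"mortality"``.
    d : float
        Mortality increment carried by new non-lethal mutations.
    effect_mode : str
        ``"from_age"``: a triggered mortality increment applies every step
        from the trigger onward; ``"at_age"``: only in the step during
        which the trigger is first reached.
    pleiotropy : float
        Fecundity multiplier carried by new mutations (``alpha``).
    reverse_rate : float
        Per-allele probability of reversion to wild type at gamete
        formation.
    F_max : float
        Per-capita recruitment cap (offspring per adult per unit age);
        ``inf`` means recruitment always refills the census to N.
    somatic_mode : bool
        Expression triggers are somatic stages instead of ages.
    stage_advance_prob : float
        Per-step probability that an individual's somatic stage increments.
    init_max_age : float
        Maximum age at death already fixed at initialization (``inf`` for a
        nonsenescent founding population).
    initial_loci : tuple
        ``(MutationLocus, copies)`` pairs seeded into the founding
        population, one heterozygous copy per randomly chosen carrier.
    age_init : str
        ``"stationary"`` (truncated exponential with rate ``mu``) or
        ``"uniform"`` founder age distribution.
    seed : int
        RNG seed; runs are bit-reproducible given the config.
    T_max : int
        Horizon in steps.
    record_every : int
        Thinning of the recorded time series.
    stop_on_absorption : bool
        With ``U = 0``, stop once no locus segregates (fixation/loss runs).
    """

    N: int = 300
    mu: float = 0.46
    dt: float = 1.0
    U: float = 0.05
    age_grid_delta: float = 1.0
    max_expr_age: float = 36.0
    effect: str = "lethal"
    d: float = 0.1
    effect_mode: str = "from_age"
    pleiotropy: float = 1.0
    reverse_rate: float = 0.0
    F_max: float = math.inf
    somatic_mode: bool = False
    stage_advance_prob: float = 1.0
    init_max_age: float = math.inf
    initial_loci: tuple = ()
    age_init: str = "stationary"
    seed: int = 0
    T_max: int = 8000
    record_every: int = 1
    stop_on_absorption: bool = False

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if not self.mu > 0 or not self.dt > 0:
            raise ValueError("mu and dt must be > 0")
        for name in ("U", "reverse_rate", "stage_advance_prob"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0,1], got {p}")
        if self.age_grid_delta < 0:
            raise ValueError("age_grid_delta must be >= 0")
        if not self.max_expr_age > 0:
            raise ValueError("max_expr_age must be > 0")
        if self.effect not in ("lethal", "mortality"):
            raise ValueError(f"unknown effect {self.effect!r}")
        if self.effect == "mortality" and not 0 < self.d <= 1:
            raise ValueError("d must be in (0,1]")
        if self.effect_mode not in ("from_age", "at_age"):
            raise ValueError(f"unknown effect_mode {self.effect_mode!r}")
        if self.pleiotropy < 0:
            raise ValueError("pleiotropy must be >= 0")
        if not self.F_max > 0:
            raise ValueError("F_max must be > 0")
        if self.age_init not in ("stationary", "uniform"):
            raise ValueError(f"unknown age_init {self.age_init!r}")
        if self.T_max < 1 or self.record_every < 1:
            raise ValueError("T_max and record_every must be >= 1")

    @property
    def mu_step(self) -> float:
        """Per-step extrinsic death probability ``1 - exp(-mu*dt)``."""
        return -math.expm1(-self.mu * self.dt)


@dataclass
class PopulationState:
    """Mutable simulation state: living individuals and segregating loci.

    Rows of ``genotype`` are living individuals; columns are segregating
    loci, values are mutant-allele counts in {0, 1, 2}; the ``loc_*``
    arrays hold per-locus attributes parallel to the columns.
    ``fixed_kill_age`` is the earliest expression trigger among lethal loci
    already fixed and compacted out of the matrix (age units; stages in
    somatic mode).
    """

    ages: np.ndarray  # float, age units
    stages: np.ndarray  # int
    genotype: np.ndarray  # int8, (n_alive, n_loci)
    loc_id: np.ndarray  # int64
    loc_trig: np.ndarray  # float
    loc_kind: np.ndarray  # int8: _LETHAL or _MORTALITY
    loc_d: np.ndarray  # float
    loc_pleio: np.ndarray  # float
    loc_origin: np.ndarray  # int64
    rng: np.random.Generator
    time: int = 0
    fixed_kill_age: float = math.inf
    fixation_events: list = field(default_factory=list)  # (locus_id, time, trigger)
    recorded_fixed: set = field(default_factory=set)
    next_locus_id: int = 0
    any_pleiotropy: bool = False

    @property
    def n_alive(self) -> int:
        return self.ages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotype.shape[1]

    @property
    def extinct(self) -> bool:
        return self.n_alive < 2

    @property
    def loci(self) -> list:
        """Registry view of the currently segregating loci."""
        return [
            MutationLocus(
                id=int(self.loc_id[j]),
                expression_trigger=float(self.loc_trig[j]),
                effect="lethal" if self.loc_kind[j] == _LETHAL else "mortality",
                d=float(self.loc_d[j]),
                pleiotropy=float(self.loc_pleio[j]),
                origin_time=int(self.loc_origin[j]),
            )
            for j in range(self.n_loci)
        ]

    def fecundity_weights(self) -> np.ndarray:
        """Per-individual fecundity weight: product of carried pleiotropies."""
        if self.n_loci and self.any_pleiotropy:
            return np.prod(
                np.where(self.genotype > 0, self.loc_pleio[None, :], 1.0), axis=1
            )
        return np.ones(self.n_alive)


@dataclass
class SimRecord:
    """Recorded time series and summary events of one run."""

    config: SimConfig
    times: np.ndarray
    census: np.ndarray
    n_segregating: np.ndarray
    fixed_max_age: np.ndarray  # min expression trigger among fixed lethals
    mean_fecundity_weight: np.ndarray
    fixation_events: list
    extinction_time: Optional[int] = None

    def summary(self) -> dict:
        return {
            "final_census": int(self.census[-1]) if len(self.census) else 0,
            "final_fixed_max_age": float(self.fixed_max_age[-1])
            if len(self.fixed_max_age)
            else math.inf,
            "n_fixations": len(self.fixation_events),
            "extinction_time": self.extinction_time,
            "seed": self.config.seed,
        }


# ---------------------------------------------------------------------------


def _empty_loci():
    return dict(
        loc_id=np.empty(0, dtype=np.int64),
        loc_trig=np.empty(0, dtype=float),
        loc_kind=np.empty(0, dtype=np.int8),
        loc_d=np.empty(0, dtype=float),
        loc_pleio=np.empty(0, dtype=float),
        loc_origin=np.empty(0, dtype=np.int64),
    )


def init_population(config: SimConfig) -> PopulationState:
    """Found a population of ``N`` individuals.

    Founder ages are drawn from the stationary age distribution — an
    exponential with rate ``mu`` truncated at ``init_max_age`` — or
    uniformly with ``age_init="uniform"``; ages are discretized to
    multiples of ``dt``.  ``initial_loci`` seeds pre-existing variants at
    given copy numbers; otherwise the founders are mutation-free.
    """
    rng = np.random.default_rng(config.seed)
    N = config.N
    cap = config.init_max_age
    if config.age_init == "stationary":
        if math.isinf(cap):
            ages = rng.exponential(1.0 / config.mu, size=N)
        else:
            u = rng.random(N)
            ages = -np.log1p(u * np.expm1(-config.mu * cap)) / config.mu
    else:
        hi = cap if math.isfinite(cap) else 3.0 / config.mu
        ages = rng.random(N) * hi
    ages = np.floor(ages / config.dt) * config.dt
    arrays = _empty_loci()
    cols = []
    next_id = 0
    for locus, copies in config.initial_loci:
        if not isinstance(locus, MutationLocus):
            raise ValueError("initial_loci entries must be (MutationLocus, copies)")
        if not 1 <= copies <= N:
            raise ValueError(f"copies must be in [1, N], got {copies}")
        col = np.zeros(N, dtype=np.int8)
        col[rng.choice(N, size=copies, replace=False)] = 1
        cols.append(col)
        arrays["loc_id"] = np.append(arrays["loc_id"], next_id)
        arrays["loc_trig"] = np.append(arrays["loc_trig"], locus.expression_trigger)
        arrays["loc_kind"] = np.append(
            arrays["loc_kind"],
            np.int8(_LETHAL if locus.effect == "lethal" else _MORTALITY),
        )
        arrays["loc_d"] = np.append(arrays["loc_d"], locus.d)
        arrays["loc_pleio"] = np.append(arrays["loc_pleio"], locus.pleiotropy)
        arrays["loc_origin"] = np.append(arrays["loc_origin"], 0)
        next_id += 1
    genotype = np.stack(cols, axis=1) if cols else np.zeros((N, 0), dtype=np.int8)
    return PopulationState(
        ages=ages,
        stages=np.zeros(N, dtype=np.int64),
        genotype=genotype,
        rng=rng,
        fixed_kill_age=config.init_max_age,
        next_locus_id=next_id,
        any_pleiotropy=bool(np.any(arrays["loc_pleio"] != 1.0))
        or config.pleiotropy != 1.0,
        **arrays,
    )


def somatic_advance(state: PopulationState, config: SimConfig) -> PopulationState:
    """Advance somatic stages stochastically (in place).

    Each living individual's stage increments with probability
    ``stage_advance_prob`` per step, so the expected stage after ``t``
    steps is ``t * stage_advance_prob``; ``stage_advance_prob = 1``
    recovers the chronological-age model (stage == age in steps).
    """
    if not config.somatic_mode:
        raise ValueError("somatic_advance requires somatic_mode=True")
    adv = state.rng.random(state.n_alive) < config.stage_advance_prob
    state.stages[adv] += 1
    return state


def fixed_lethal_max_age(state: PopulationState) -> float:
    """Earliest expression trigger among lethal loci fixed in the living.

    This is the population's maximum age at death; ``inf`` when no lethal
    locus is fixed.  A locus counts as fixed when every living individual
    carries two mutant alleles.  (In somatic mode the value is on the
    stage scale.)
    """
    best = state.fixed_kill_age
    if state.n_loci and state.n_alive:
        fixed = (state.genotype.min(axis=0) == 2) & (state.loc_kind == _LETHAL)
        if fixed.any():
            best = min(best, float(state.loc_trig[fixed].min()))
    return best


def _clock(state: PopulationState, config: SimConfig) -> np.ndarray:
    return state.stages if config.somatic_mode else state.ages


def _draw_trigger(rng: np.random.Generator, config: SimConfig, size: int) -> np.ndarray:
    """New expression triggers: uniform on the age grid up to max_expr_age."""
    if config.somatic_mode:
        hi = max(1, int(round(config.max_expr_age / config.dt)))
        return rng.integers(1, hi + 1, size=size).astype(float)
    if config.age_grid_delta > 0:
        n_grid = int(math.floor(config.max_expr_age / config.age_grid_delta))
        if n_grid < 1:
            raise ValueError("age grid has no point at or below max_expr_age")
        return config.age_grid_delta * rng.integers(1, n_grid + 1, size=size)
    return rng.random(size) * config.max_expr_age


def step(state: PopulationState, config: SimConfig) -> PopulationState:
    """Advance the population one time step (in place).

    Order of events: ageing; extrinsic + triggered-mortality deaths;
    lethal-expression deaths; somatic-stage advance; density-dependent
    recruitment (capped by ``F_max`` when finite) with Mendelian
    inheritance, reversion and de novo mutation at gamete formation;
    compaction of lost and (without reversion) fixed loci.
    """
    if state.extinct:
        raise ValueError("cannot step an extinct population")
    rng = state.rng
    state.time += 1
    state.ages += config.dt
    n = n_start = state.n_alive  # offspring are produced throughout the step,
    # so the recruitment cap counts individuals alive at its start
    G = state.genotype
    L = G.shape[1]
    clock = _clock(state, config)

    # -- deaths -----------------------------------------------------------
    p_death = np.full(n, config.mu_step)
    if L:
        mort = state.loc_kind == _MORTALITY
        if mort.any():
            trig_m = state.loc_trig[mort]
            if config.effect_mode == "from_age":
                expressed = clock[:, None] >= trig_m[None, :]
            elif config.somatic_mode:
                expressed = clock[:, None] == trig_m[None, :]
            else:
                prev = clock - config.dt
                expressed = (clock[:, None] >= trig_m[None, :]) & (
                    prev[:, None] < trig_m[None, :]
                )
            add = ((G[:, mort] > 0) & expressed) @ state.loc_d[mort]
            p_death = np.minimum(p_death + add, 1.0)
    dead = rng.random(n) < p_death
    if L:
        lethal = state.loc_kind == _LETHAL
        if lethal.any():
            dead |= (
                (G[:, lethal] > 0) & (clock[:, None] >= state.loc_trig[lethal][None, :])
            ).any(axis=1)
    if math.isfinite(state.fixed_kill_age):
        dead |= clock >= state.fixed_kill_age
    alive = ~dead
    state.ages = state.ages[alive]
    state.stages = state.stages[alive]
    state.genotype = G = np.ascontiguousarray(G[alive])
    n = int(alive.sum())

    # -- somatic stage dynamics ------------------------------------------
    if config.somatic_mode and n:
        adv = rng.random(n) < config.stage_advance_prob
        state.stages[adv] += 1

    # -- recruitment ------------------------------------------------------
    if n >= 2:
        vacancies = config.N - n
        if math.isfinite(config.F_max):
            cap = config.F_max * n_start * config.dt
            k = int(math.floor(cap))
            if rng.random() < cap - k:
                k += 1
            vacancies = min(vacancies, k)
        if vacancies > 0:
            if L and state.any_pleiotropy:
                w = state.fecundity_weights()
                wsum = w.sum()
                prob = w / wsum if wsum > 0 else None
            else:
                prob = None
            p1 = rng.choice(n, size=vacancies, p=prob)
            p2 = rng.choice(n, size=vacancies, p=prob)
            clash = p1 == p2  # force two distinct parents
            while clash.any():
                p2[clash] = rng.choice(n, size=int(clash.sum()), p=prob)
                clash = p1 == p2
            if L:
                child = (rng.random((vacancies, L)) * 2 < G[p1]).astype(np.int8)
                child += (rng.random((vacancies, L)) * 2 < G[p2]).astype(np.int8)
                if config.reverse_rate > 0:
                    child -= rng.binomial(child, config.reverse_rate).astype(np.int8)
            else:
                child = np.zeros((vacancies, 0), dtype=np.int8)
            mutant = np.flatnonzero(rng.random(vacancies) < config.U)
            if mutant.size:
                m = mutant.size
                triggers = _draw_trigger(rng, config, m)
                new_cols = np.zeros((vacancies, m), dtype=np.int8)
                new_cols[mutant, np.arange(m)] = 1
                child = np.concatenate([child, new_cols], axis=1)
                G = np.concatenate([G, np.zeros((n, m), dtype=np.int8)], axis=1)
                ids = state.next_locus_id + np.arange(m)
                state.next_locus_id += m
                kind = _LETHAL if config.effect == "lethal" else _MORTALITY
                state.loc_id = np.concatenate([state.loc_id, ids])
                state.loc_trig = np.concatenate([state.loc_trig, triggers])
                state.loc_kind = np.concatenate(
                    [state.loc_kind, np.full(m, kind, dtype=np.int8)]
                )
                state.loc_d = np.concatenate([state.loc_d, np.full(m, config.d)])
                state.loc_pleio = np.concatenate(
                    [state.loc_pleio, np.full(m, config.pleiotropy)]
                )
                state.loc_origin = np.concatenate(
                    [state.loc_origin, np.full(m, state.time, dtype=np.int64)]
                )
            state.genotype = np.concatenate([G, child], axis=0)
            state.ages = np.concatenate([state.ages, np.zeros(vacancies)])
            state.stages = np.concatenate(
                [state.stages, np.zeros(vacancies, dtype=np.int64)]
            )

    _compact(state, config)
    return state


def _compact(state: PopulationState, config: SimConfig) -> None:
    """Drop lost loci; record fixations; fold fixed lethals when irreversible."""
    if not state.n_loci or not state.n_alive:
        return
    G = state.genotype
    keep = G.max(axis=0) > 0
    fixed = G.min(axis=0) == 2
    if fixed.any():
        for j in np.flatnonzero(fixed):
            lid = int(state.loc_id[j])
            if lid not in state.recorded_fixed:
                state.recorded_fixed.add(lid)
                state.fixation_events.append(
                    (lid, state.time, float(state.loc_trig[j]))
                )
            if config.reverse_rate == 0 and state.loc_kind[j] == _LETHAL:
                state.fixed_kill_age = min(
                    state.fixed_kill_age, float(state.loc_trig[j])
                )
                keep[j] = False  # column now uninformative
            # irreversibly fixed mortality loci keep their (constant) column
            # so triggered expression still applies; with reversion enabled
            # all fixed columns stay mutable
    if not keep.all():
        state.genotype = np.ascontiguousarray(G[:, keep])
        state.loc_id = state.loc_id[keep]
        state.loc_trig = state.loc_trig[keep]
        state.loc_kind = state.loc_kind[keep]
        state.loc_d = state.loc_d[keep]
        state.loc_pleio = state.loc_pleio[keep]
        state.loc_origin = state.loc_origin[keep]


def run(config: SimConfig) -> SimRecord:
    """Run the simulation to ``T_max`` steps or extinction.

    Deterministic given ``config`` (including ``seed``).  The recorded
    ``fixed_max_age`` series is the earliest expression trigger among
    lethal loci fixed so far (``inf`` until the first fixation), i.e. the
    population's evolving maximum age at death.
    """
    state = init_population(config)
    times, census, nseg, fmax, meanw = [], [], [], [], []
    extinction_time: Optional[int] = None

    def record() -> None:
        times.append(state.time)
        census.append(state.n_alive)
        nseg.append(state.n_loci)
        fmax.append(fixed_lethal_max_age(state))
        meanw.append(float(state.fecundity_weights().mean()) if state.n_alive else 0.0)

    record()
    for _ in range(config.T_max):
        step(state, config)
        if state.extinct:
            extinction_time = state.time
            record()
            break
        if state.time % config.record_every == 0:
            record()
        if config.stop_on_absorption and config.U == 0 and state.n_loci == 0:
            if state.time % config.record_every != 0:
                record()
            break
    return SimRecord(
        config=config,
        times=np.array(times),
        census=np.array(census),
        n_segregating=np.array(nseg),
        fixed_max_age=np.array(fmax),
        mean_fecundity_weight=np.array(meanw),
        fixation_events=list(state.fixation_events),
        extinction_time=extinction_time,
    )
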