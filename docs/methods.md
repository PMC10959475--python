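# Methods

## Model

We consider a density-regulated population at its stationary age
distribution, so that lifetime reproductive success is one:

LRS = ∫_{x_min}^{X} k(t) dt = 1,

with `x_min` the age at first reproduction, `X` the maximum age at death
(possibly infinite) and `k(t)` the age-specific reproductive success. For
the closed forms we take `k(t) = F e^{−μt}`: survival declines with the
age-independent extrinsic mortality rate μ, fecundity `F` is the same at
all ages, and stationarity pins
`F = μ / (e^{−μ·x_min} − e^{−μX})` (so `F > μ` for finite `X`; `F = μ` in a
nonsenescent population with `x_min = 0`). The quadrature oracle in the
test suite verifies stationarity without relying on the closed forms.

A dominant mutation lethal at age `x ∈ [x_min, X]`, with fecundity
multiplier α ≥ 0, has `LRS_mut = α ∫_{x_min}^{x} k(t) dt`, hence the
selection coefficient

s(x) = α (e^{−μ·x_min} − e^{−μx}) / (e^{−μ·x_min} − e^{−μX}) − 1,

strictly increasing from −1 at `x = x_min` to `α − 1` at `x = X`. The
survival factor `e^{−μ·x_min}` cancels, so `s` depends only on the ages
relative to `x_min`; this translation invariance is how the implementation
generalizes every closed form to `x_min > 0`.

**Drift barrier and critical age.** The mutation can fix by drift when
`s(x) > −1/Ne` (strictly: ties do not invade). Solving `s(x̂*) = −1/Ne`
gives, at `x_min = 0`,

x̂* = (1/μ) ln( αNe / (Ne(α−1) + 1 + e^{−μX}(Ne−1)) ),

provided `α − 1 > −1/Ne` (otherwise no age is invadable). Limits:
`x̂* → ln(Ne)/μ` as `X → ∞` with α = 1, and `x̂* → 0` as `X → 0⁺`. The
printed form of this expression in our source material is typographically
ambiguous; the implementation is the algebraic solution of
`s(x̂*) = −1/Ne` and is verified against both limits and against an
exhaustive lattice search over `s`.

**Sequential fixation.** Since each fixation resets the stationary
fecundity upward, the critical age recomputed at the new maximum age at
death is lower still. `iterate_accumulation` idealizes this as
`X_{n+1} = x̂*(X_n)` (each invading mutation lethal exactly at the current
critical age; an optional ε offset implements "slightly above"). Near
`x_min` the map contracts by `(Ne−1)/Ne` per step, so convergence to
semelparity is geometric but slow for large `Ne`.

**Grained ages.** When lethal effects can occur only at ages
`x_min + jδ`, each step takes the smallest grid age strictly inside
`(x̂*(X_n), X_n)` and halts when that window contains no grid point. The
halting age lies in the closed-form interval
`[upper − δ, upper]` with
`upper = x_min + (1/μ) ln( (Ne(α e^{μδ} − 1) + 1) / (Ne(α−1) + 1) )`,
the root of `X − x̂*(X) = δ`. Which grid age inside the interval is
realized depends on the grid phase; `grained_accumulation` resolves it for
the grid anchored at `x_min` (anchoring is a config choice, since only the
spacing is prescribed by the theory).

## Numerical choices

- Closed forms use `expm1`/`log1p` throughout; infinite `X` is an explicit
  branch (`e^{−μX} → 0`), never a large sentinel.
- Invasion threshold ties (`s = −1/Ne` to the last ulp) resolve to
  "no invasion"; the grained grid search guards the floating-point
  boundary by stepping past grid ages numerically equal to `x̂*`.
- Test oracles: adaptive quadrature (absolute tolerance 1e−13), binary
  search on a 1e−6 age lattice (exploiting only monotonicity of `s`), and
  Brent root bracketing at 1e−13; cross-checks assert agreement at 1e−10.
- Trajectory iteration stops within `stop_tol` (default 1e−6 age units) of
  `x_min`, at `max_steps`, or when no age is invadable.

## Individual-based model

The simulator makes the drift explicit that the analytic iteration
idealizes. A well-mixed diploid population of target census `N` evolves in
discrete steps of length `dt`:

1. ageing by `dt`;
2. extrinsic death with probability `mu_step = 1 − e^{−μ·dt}`, plus `d`
   per triggered non-lethal (mortality-increment) locus carried — either
   from the trigger onward or only in the step the trigger is reached
   (both variants are implemented; which one real systems follow is
   unresolved, so it is a config switch);
3. dominant lethal expression: carriers whose age (or somatic stage) has
   reached a lethal locus's trigger die, as does anyone reaching the
   earliest *fixed* lethal trigger;
4. optional somatic-stage advance with probability `stage_advance_prob`
   (expected stage after `t` steps is `t·stage_advance_prob`;
   probability 1 reduces to the chronological-age model);
5. recruitment: vacancies up to `N` are refilled by offspring of two
   distinct parents sampled with weight proportional to the product of
   carried pleiotropy multipliers; each parental allele transmits with
   probability half (unlinked loci), reverts with probability
   `reverse_rate`, and each offspring carries one new mutation with
   probability `U`, its expression age uniform on the grain-δ grid up to
   `max_expr_age`. With a finite per-capita cap `F_max`, recruits are
   limited to `F_max · n · dt` where `n` counts individuals alive at the
   step start — reproduction happens throughout the interval, so the
   allowance accrues to everyone who began the step alive — and deaths
   may go uncompensated.

Fixed lethal loci (both alleles in every living individual) are folded
into a scalar "earliest fixed kill age" when reversion is off; with
reversion on, fixed columns stay mutable. The recorded maximum age at
death is the earliest trigger among strictly fixed lethals, matching the
analytic phenotype definition. Extinction is a census below 2.

### What the default battery emulates

The four regimes (`experiments.default_battery`, N = 300, 20 replicates)
share μ = 0.46 — the mortality rate of the analytic illustrations — unit
steps, U = 0.05 (mutation supply is assumed not limiting; the analytic
collapse presumes the relevant mutations arise), and
`max_expr_age = 36 ≈ 3·ln(N)/μ`, leaving a "wall of death" region of
effectively unexpressed ages:

- **fine** (grain = `dt`): the maximum age at death ratchets steadily
  down; the replicate-median trajectory declines through the run.
- **coarse** (grain 4): the ratchet halts; the plateau sits above the
  fine-grain outcome. (The day/year contrast of the motivating biology is
  scaled here to a 1:4 grain ratio to keep the run lengths proportionate.)
- **capped** (grain = `dt` = 0.5, `F_max = 0.416`): viability requires the
  per-step birth allowance `F_max·dt` to exceed the stationary per-step
  death fraction, which rises from `mu_step ≈ 0.2054` (nonsenescent) to
  ≈0.2088 at a maximum age at death of 9; the cap's allowance of 0.2080
  sits between them, so the census is stable while the population is
  long-lived and collapses — in every replicate — once the ratchet
  approaches its halting age. The cap was placed by this analytic
  bracketing, not fitted to simulation output.
- **reverse** (per-allele reversion 1e−4): population-scaled reversion
  `2N·r ≪ 1`. Reversion makes *strict* fixation porous, but because many
  lethals accumulate at adjacent ages, reverting the earliest-acting one
  extends life only to the next trigger, so the decline persists. A rate
  of order 1/(2N) or larger would instead prevent strict fixation
  outright at this census size — that is a property of the fixation
  metric, not of the mortality phenotype.

`Ne` in analytic comparisons is set to the census `N`; with overlapping
generations and multinomial reproduction the realized effective size is
smaller (the observed plateaus sit below the `Ne = N` prediction,
consistent with `Ne ≈ N/2`), and we treat the identification as an
acknowledged approximation rather than calibrating it.

### What the generator does not emulate

Real genomes have linkage, recessive and partially dominant effects,
continuous effect-size distributions, environment-dependent expression and
finite mutational target sizes; the simulator has none of these. Passing
tests show that the drift-ratchet mechanism operates and halts exactly as
the theory predicts *within this idealization* — they do not show that
real populations senesce this way.

## Problem sizes

The battery runs 20 replicates per regime at N = 300 over horizons of
8000 steps (24000 half-unit steps for the capped cell; it typically ends
in extinction much earlier), and the neutral control runs 10⁴
fixation/loss replicates at N = 20 — sizes chosen so the full suite
completes comfortably on a single core while leaving the qualitative
contrasts far outside sampling noise.

## Known limitations

- The sequential-fixation iteration treats fixation as instantaneous and
  ignores segregation variance; the simulator shows the idealization is
  qualitatively right but quantitatively optimistic about the plateau age
  (drift pushes it lower through the reduced effective size).
- The equilibrium interval brackets, but does not pick, the realized
  halting age off-grid; only the anchored-grid iteration resolves it.
- The capped-recruitment viability analysis is specific to the discrete
  step scheme; the continuous-time threshold `F_max < μ/(1−e^{−μX})` is
  recovered only as `dt → 0`.
- `x_min > 0` is supported throughout via translation invariance, but the
  grained grid is then anchored at `x_min`, which is a modeling choice.
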