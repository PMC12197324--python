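# Methods

## The models

`retrofix` implements two coupled models of host–retrovirus interaction.

### Deterministic model: virulence evolution of an exogenous retrovirus

An exogenous retrovirus (XRV) infects somatic cells and is transmitted
horizontally and maternally. A strain is described by its virus production
rate `x ≥ 0` and maternal transmission probability `m ∈ [0, 1]`. Hosts are
born at per-capita rate `b0` (logistically throttled by `1 − N_tot/K`),
uninfected hosts die at rate `v0`, and infection raises the death rate to
`vX = v0·e^x`. The super-linear cost in `x` is essential: with a linear
cost there is no interior optimum and virulence grows without bound.
Horizontal infection of an uninfected host occurs at rate `α·x·N_X/K`,
where `α` is the host contact rate (a property of host behaviour, not
under viral control). Offspring of an infected mother are infected with
probability `m`. With `p_uninf = 1 − v0/b0` the uninfected equilibrium
density, a rare strain invades iff its reproductive ratio

    R = b0·m·(1 − p_uninf)/vX + α·x·p_uninf/vX

exceeds 1. Virulence evolution is resolved by direct competition: `n`
strains with `x_i = δ·i` (reference grid `δ = 0.001`, `n = 1100`) and the
trade-off `m_i = 1 − e^(−M·x_i)` compete in the multi-strain system
(one infection per host, no recovery, no super-infection). `M` measures
how easily maternal transmission comes with virus production. The
population-weighted means ⟨x⟩ and ⟨m⟩ converge to the evolutionarily
selected strain. With `M = 0` the winner maximises `R ∝ x·e^(−x)`, i.e.
`x* = 1`, giving the analytic anchor `vX/v0 = e ≈ 2.718` and the invasion
threshold `α_c = v0·e/p_uninf ≈ 0.68` for `b0 = 1, v0 = 0.2`.

The deterministic system is scale-free in `K`; results are reported as
densities per `K`.

### Stochastic model: spread of an endogenous retrovirus

An endogenous retrovirus (ERV) is a germline insertion, transmitted
genetically at `L` unlinked diploid loci and multiplying within a genome
by transposition at rate `r·l·(1 − l/2L)` for an individual with `l`
copies. Carriers die at rate `vE = v0·e^y`; doubly afflicted individuals
(carrier and XRV-infected) die at `max(vX, vE)`. Carriers may enjoy
receptor interference against the XRV: their horizontal infection rate is
`β·x·(N_X + N_EX)/K` with `β ∈ [0, α]` (`β = 0`: complete resistance),
and maternal transmission to carrier offspring is reduced to `m·β/α`.

The population is a fixed array of `K` slots, each empty or holding an
individual with a sex, an infection flag and a 2L-allele genome. Events
(birth with Mendelian inheritance, per-type death, horizontal infection,
transposition) are drawn by the exact Gillespie algorithm: exponential
waiting times at the total rate, events proportional to class rates,
uniform choice within a class (transposition uses per-individual weights).
Births occur at `2·b0·(1 − N_tot/K)` per female with a uniformly chosen
male as father — equivalent, at the population level, to per-capita rate
`b0` with purely maternal transmission.

A replicate starts from the stationary densities `(p0, pX)` of the
deterministic two-compartment model (or the virus-free equilibrium),
Bernoulli-sampled per slot, converts one individual of the appropriate
type (X when the XRV is present, else 0) into a single-copy carrier, and
runs to an absorbing state: **fixation** (no individual without a copy —
beyond this point the copy number can only grow by transposition, so the
run is stopped here), **loss**, **clearance** (the XRV was eliminated
strictly before the insertion was lost), whole-population **extinction**,
or censoring at `t_max`.

## Parameters and defaults

| parameter | meaning | default | units |
|---|---|---|---|
| `b0` | per-capita birth rate (2·b0 per female) | 1.0 | 1/time |
| `v0` | uninfected death rate (mean lifespan 1/v0) | 0.2 | 1/time |
| `K` | carrying capacity | 1000 (stochastic) | individuals |
| `α` | host contact rate | 1.0 | 1/time |
| `x`, `m` | XRV production rate / maternal transmission | evolved pair | – |
| `M` | ease of maternal transmission | 0 | – |
| `y` | ERV virulence (`vE = v0·e^y`) | 0 | – |
| `r` | transposition rate per copy | 0.1 | 1/time |
| `β` | contact rate for carriers | 1.0 | 1/time |
| `L` | insertable diploid loci | 10 | – |
| `t_max` | censoring horizon | 1e5 | time |

`r/v0 < 1` (fewer than one transposition per lifetime) is the biologically
plausible regime; `r = 1` is an extreme upper bound.

## Numerical choices

* **Integrator.** Fixed-step classic RK4 with `h = 0.01`; all rates are
  O(1), so the local error is far below the steady-state tolerances.
  Negative densities from truncation error are clipped to zero, and
  densities below 1e-250 are flushed to zero — exponentially decaying
  strains otherwise enter subnormal-float territory, which slows the
  integration by an order of magnitude without changing any result.
* **Competition convergence.** Steady state is declared when ⟨x⟩ and ⟨m⟩
  each change by less than 1e-6 over a 100-time-unit window (horizon
  1e5). The mean approaches its limit like c/t, so this triggers around
  t ≈ 4×10⁴ with ⟨x⟩ within ~5×10⁻⁴ of the limit — half the strain-grid
  spacing. A tolerance of 1e-7 would need a horizon ≳1.3×10⁵ for no gain
  at grid resolution.
* **Invasion threshold.** `critical_alpha` bisects `max_i R_i(α) = 1`
  over the strain grid — survival when rare is governed by `R`, so this
  equals the threshold of the full competition at a fraction of the cost.
  The competition-based scan (`critical_alpha_scan`) is retained as a
  cross-check; it forces the full horizon because the strain mix
  stabilises long before a slowly decaying total density does.
* **Means of a vanishing virus.** When the infected density falls below
  1e-12 per K, ⟨x⟩ and ⟨m⟩ are reported as NaN (no meaningful virus).
* **Event bookkeeping.** Per-class swap-remove index lists give O(1)
  uniform sampling; copy-number sums `Σl` and `Σl²` are maintained
  incrementally (exact in integers), so the transposition rate never
  drifts. A debug `audit()` recounts everything from the slots.
* **Degenerate inputs.** Births require at least one male (the total
  birth rate is zero when `N_M = 0`); `m > 0` with `α = 0` is rejected at
  validation (the carrier reduction `m·β/α` would be undefined); an
  initial state in which every individual already carries the insertion
  is classified as fixation at t = 0 (consistent with the definition of
  fixation as "no individual without a copy").
* **Whole-population extinction** ends a replicate with its own outcome
  label and is excluded from the numerator and denominator of `p_fix`
  (it is vanishingly rare at `K = 1000`).
* **Seeding.** Replicate `i` of a batch uses seed `base + i`; one
  generator per replicate drives initialisation, and a derived seed
  drives the compiled event loop. Results are independent of execution
  order and reproducible across runs.

## What the simulations do and do not emulate

Initial conditions are idealised stationary states of the deterministic
model; the XRV is assumed to have evolved to its optimum before the
insertion appears. The model omits, by design: mutation of the ERV's `r`
or `y` during spread, an infectious intermediate ERV stage, host defence
systems (their net effect is folded into `r`), age structure, linkage
between loci, recombination between ERV and XRV, and competition among
multiple ERV types. Passing tests therefore demonstrate correctness of
this idealised model, not predictions for any particular natural system.

## Problem sizes used in the test suite

Stochastic checks run at 2×10³ replicates per parameter point (binomial
tolerances are computed at the replicate count actually used), the
neutral-control estimate at 2×10⁴ replicates, and the tiny-population
oracle comparison at 10⁵ replicates against an exactly solved
continuous-time Markov chain (K ≤ 8, L = 1, lumped over sex × genotype
classes, whose dynamics depend only on class counts). Deterministic
anchors run on the full 1100-strain grid; qualitative orderings of the
evolved (x, m) locus use a 10× coarser grid, which shifts the evolved
pairs by less than the assertions' margins.

## Known limitations

* The fixation stop rule ("every individual has at least one copy")
  slightly overstates allele fixation when `r = 0` (the allele could
  still drift out from frequency ≈ 0.97); the effect is ~3% relative,
  well inside the statistical tolerances used.
* `critical_alpha_scan` resolves the threshold only to its α-grid.
* With `m` close to 1 and `x` close to 0 the competition's convergence
  slows (near-neutral strain mixtures); the `converged` flag reports
  honestly whether the tolerance was met.
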