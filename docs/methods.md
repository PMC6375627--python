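# Methods

This note records the model, the numerical choices behind each module, and
what the package's validation does and does not establish.

## The model

A well-mixed population of `k ≥ 2` types lives in a habitat of size `Ω`
(individuals per unit density); counts are `N_i = Ω x_i`.  Type 1 (index 0)
is the social actor.  The social action is *indiscriminate*: every individual
— actor or not — experiences the same per-capita birth rate `b(x)` and death
rate `m(x)`, which may depend on the full density vector; only through the
density of actors does the trait act.  Actors additionally pay a cost
`ε c(x)` on their per-capita growth rate, and mutation converts a living
individual between types at per-capita rate `μ` (per ordered type pair).

Altruism = the action enhances recipients' vital rates (raises `b` or lowers
`m`); spite = the opposite.  Only density dependence is supported: the
framework would admit rates depending on an external environmental state, but
no dynamics for such a state are specified anywhere, so the package does not
model one.

Built-in two-type families (`n = x₁ + x₂`):

| family | b | m | c | constraints |
|---|---|---|---|---|
| `death_rate` | `β(1−n)` | `d(1 + νx₁/n)` | 0 | `ν ∈ (−1,1)`, `β > d(1+|ν|)` |
| `birth_altruism` | `β + νx₁` | `d + κ₁n + κ₂n²` | 0 | `ν ≥ 0`, `β > d > 0` |
| `birth_spite` | `β(1 − νx₁/(n+a))` | `d + κ₁n + κ₂n²` | 0 | `ν ∈ [0,1]`, `a > 0` |
| `altruism_model1` | `r + νx₁` | `κn` | `r` | `κ > ν > 0`, `r > 0` |
| `altruism_model2` | `β + νx₁` | `d + κn` | `r = β−d` | `κ > ν > 0`, `β > d > 0` |

The last two are a deliberately matched pair: identical per-capita growth
`b − m` everywhere (hence identical deterministic dynamics, identical
quasi-equilibrium `n(p) = r/(κ−νp)` and identical frequency drift `α(p)`),
but model 2 has strictly larger turnover, making `T/n` decrease in `p`
instead of being constant.  Everything that distinguishes their evolutionary
outcomes is demographic noise.

Parameter validity intervals are enforced at construction with error
messages naming the violated constraint.  Rate formulas that go negative on
stochastic excursions (e.g. logistic birth above carrying capacity) are
clamped at zero; clamps are counted per model and logged once, not per
event.  The actor's cost is placed on its death rate by default (keeping all
channel rates non-negative); a `cost_on_birth` switch subtracts it from the
birth rate instead.  At the order kept by the diffusion reduction the two
placements are equivalent — the reduction only sees the growth-rate
difference `−εc`.

`make_trait_ladder` builds `k`-type generalizations in which type `i`
carries strength `ν_i` and the social terms sum over actors
(e.g. `m = d(1 + Σ ν_i x_i / n)`); these are used for multi-trait
competition experiments and are cost-free by construction.

## Slow manifold and diffusion coefficients

With weak selection, rare mutation and a large habitat, demographic dynamics
relax quickly onto the curve of ecological equilibria `b = m`, leaving the
actor frequency `p` as the slow variable.  `n(p)` is computed as the stable
positive root of `b − m = 0` at fixed `p` (bracketed scan over
`(0, n_max]` with `n_max` auto-expanded by doubling until `b < m`; brentq
refinement to `xtol = 1e−14`; stability decided by the finite-difference sign
of `∂(b−m)/∂n`).  Zero stable roots raise an error; multiple stable roots
demand an explicit bracket rather than guessing.  Grid evaluations walk the
manifold by continuity, re-bracketing around the previous root.  The
quasi-equilibrium is always computed at `ε = 0`: the cost is a higher-order
perturbation of the manifold and enters only the drift.

Derivatives for the `T/n` decomposition use centred finite differences
(`h = 1e−5` for scalar queries, `np.gradient` on grids); boundary points fall
back to one-sided stencils and are flagged as lower accuracy.  No symbolic
differentiation is used, so arbitrary user-supplied rate functions work.

## Stationary distribution

For a 1-D diffusion the stationary density is
`π ∝ σ⁻² exp(∫ 2α/σ²)`.  Substituting the coefficients shows the exponent
integrand splits as `h(p)/p − h(p)/(1−p) − e(p)` with
`h = 2μΩn/T` and `e = 2εcΩn/T`, giving *pure power-law boundary behaviour*
with exponents `a₀ = h(0) − 1`, `a₁ = h(1) − 1`.  The implementation leans on
this structure:

- the singular parts are integrated analytically; only the smooth remainder
  is integrated numerically (cumulative Simpson on a 2048-interval grid),
  anchored at `p = 1/2` so nothing blows up near the boundaries;
- normalization and the occupancy mass are computed per half-interval in log
  space: Gauss–Jacobi quadrature with the exact boundary exponent as the
  quadrature weight when that exponent is ≤ 5 (this treats integrable
  divergences exactly — U-shaped densities pose no problem), and composite
  Simpson with log-sum-exp shifting when the exponent is large and positive
  (the density then vanishes fast at that boundary and the excluded endpoint
  sliver carries mass below `(1/M)⁶`).  The split is decided per boundary, so
  mixed regimes (e.g. exponents 2.2 and 353) are handled;
- integrability is exactly `a₀ > −1` and `a₁ > −1` (i.e. `μ > 0`); the
  non-integrable case returns the diagnostic exponents and refuses to
  normalize rather than silently renormalizing.

In the neutral case the construction is symmetric by construction, so the
mass above `1/2` equals 0.5 to rounding error — the package's neutrality
checks are exact, not statistical.

Closed forms are provided for the matched pair.  For model 1,
`π ∝ p^{μΩ/κ−1}(1−p)^{μΩ/κ−1} e^{−εrΩp/κ}` — a symmetric Beta tilted against
the actor whenever `ε > 0`, which is why stochasticity can never reverse
selection there.  For model 2 the exponents were derived from the general
formula (the factor `βκ − dνp` comes from `T/n = 2(βκ − dνp)/r`):
`π ∝ p^{A−1}(1−p)^{B−1}(βκ−dνp)^G` with `A = μΩr/(βκ)`,
`B = μΩr/(βκ−dν)`, `G = r²Ωε/(dν) − A − B − 1`.  Because such derivations
are easy to get subtly wrong, the model-2 closed form is *certified* against
the general integrator (`certify_model2_closed_form`, sup relative error
< 1e−4 on [0.01, 0.99]) rather than trusted; the tests run this
certification at the shipped parameter set.

Favourability is the occupancy criterion (mass above `1/2` exceeding `1/2`);
a verdict from the analytic density is a point statement, while Monte-Carlo
verdicts from simulation carry binomial standard errors.  Shape classes:
`U` (both boundary exponents negative), `boundary-unimodal` (one-sided
divergence, or a boundary-accumulating mode pushed just interior — the
intermediate-mutation regime), `bell` (single interior mode, no divergence),
`other` (flat or multimodal).  Mode detection uses a `1e−10` tie threshold in
log density.

## Exact simulation

Direct-method Gillespie with per-event rate recomputation; no tau-leaping —
this simulator is the package's ground truth, so exactness is the point.
Channels: birth of type `i` at `N_i b(x)`, death at `N_i m(x)`, extra actor
mortality `N_a ε c(x)` (or reduced actor birth under `cost_on_birth`),
mutation `i → j` at `N_i μ` per ordered pair.  Mutation converts an existing
individual; it is not birth-with-mutation.

Randomness: one PCG64 generator per realization; ensembles spawn per-replicate
`SeedSequence` children from the master seed and record the child seeds.
The same seed reproduces the event sequence bit for bit.  Two-type built-ins
run through an allocation-free scalar fast path (~1 μs/event); generic
k-type models use a numpy loop.

Fixation estimates require `μ = 0` (otherwise the process is recurrent and
absorption is undefined); replicates hitting the event cap are excluded and
counted, with a warning above 1% exclusions; total extinction is tallied
separately and counts as non-fixation.  Occupancy histograms weight each
visited frequency by its *holding time* — the stationary density is an
occupancy measure, and per-event sampling would bias toward high-turnover
states.  A streaming accumulator supports long runs without storing
trajectories; it is tested to agree exactly with the post-hoc histogram.

## SDE integration

Euler–Maruyama throughout; no higher-order schemes.  The frequency SDE uses
coefficient tables interpolated from the manifold (4097 points) with default
`dt = 0.01/max T` and a guard at `0.1/max T`; paths are clipped to `[0, 1]`
with hits counted.  Clipping introduces no sticky absorption: with `μ > 0`
the drift at the boundary points inward, which the tests verify by fraction
of time spent exactly on the boundary.

The k-type density system is
`dx_i = x_i(b − m − εc·1[i=actor]) dt + √(x_i(b + m + εc·1[i=actor])/Ω) dW_i
+ μ(Σ_{j≠i} x_j − (k−1)x_i) dt` with independent Wiener increments per type
— the standard diffusion limit of independent birth and death channels,
pooling demographic noise as `b + m` per capita — and a reflecting floor at
zero (hits counted).  Because this noise structure is a modelling choice, it
is validated against ground truth before being used for multi-type claims:
on a two-type model its long-run occupancy reproduces the analytic
stationary mass to a few percent.

`frequency_vs_density_consistency` measures, from the same density-SDE
ensemble, the empirical drift of the frequency and of the actor *density*.
At neutrality the frequency drift is statistically zero while the density
drift is strictly positive (the population grows more after actor fixations
than it shrinks after losses).  This is the package's demonstration of why
density-level drift terms cannot be read as evolutionary success.

## Experiments

*Optimal action.*  `ν*` minimizes `T(1)/n(1)` (monomorphic actors, `p = 1`
exactly).  Closed forms (`θ = √(d/κ₂)`): altruism `ν* = κ₁ − |β − 2d|/θ`,
spite `ν* = (a+θ)(β − 2d − κ₁θ)/(βθ)`.  An independent bounded scalar
minimization (`xatol = 1e−10`) is always run alongside; for interior optima
with `β ≥ 2d` the two agree to better than 1e−6.  For `β < 2d` the
absolute value makes the printed altruism formula disagree with the true
interior minimum, which sits at `κ₁ − (β − 2d)/θ > κ₁`; the package keeps
the closed form as documented, reports both, and treats the numeric result
as authoritative (a dedicated test pins this behaviour).  Optima landing
within 1e−6 of the admissible-range edge are flagged `boundary_optimum`.

*Reversal scans.*  Favourability over an `(Ω, ε)` grid at fixed `μ`;
non-integrable cells are reported, not fatal.  The reversal boundary in `Ω`
is located by bisection, treating `Ω` as the continuous scale parameter it
is in the diffusion.  Because the matched-pair phenomenology depends jointly
on `μ` and `Ω`, the corresponding presets deliberately ship without values
for either: the user must choose them explicitly.  The package's own
scaled-down demonstration uses `μ = 0.02`, where model 2 is favoured at
`Ω = 100` and disfavoured at `Ω = 2000` while model 1 is never favoured.

*Mutation sweeps* record mass and shape across `μ`.  Note that in the
death-rate altruism family the `p = 1` boundary has tiny turnover, hence a
large effective mutation supply `2μΩn/T`; a genuinely U-shaped density
therefore requires much smaller `μ` than the bell-to-U intuition based on
`μΩ` alone suggests (at the shipped parameters, `μ ≲ 6e−5`).

*Mutation-fixation chain.*  The monomorphic transition rate is
`μ_ij N_i × (1/N_i) = μ_ij`, independent of population size; with symmetric
mutation the trait chain is uniform.  The neutral invasion probability is
`1/(Ω n(p_res))`.  Together these pin the package's most counterintuitive
calibration: pairwise invasion comparisons favour whichever trait sustains
the larger population, yet the full rare-mutation process occupies all
monomorphic states equally — trait concentration emerges only at
intermediate mutation supply, which is where the multi-type tests operate.

## Problem sizes used in validation

The test suite and the acceptance script use scaled-down ensembles chosen so
each stochastic check resolves its target at ~3 standard errors: 1500–4000
fixation replicates; pooled exact-process occupancy of 4 × 10⁴ time units
for total-variation comparisons (pilot TV ≈ 0.022 against the analytic
density, threshold 0.05); frequency-SDE occupancy of 16 × 8000 time units
(threshold 0.08); 24-replicate multi-type runs of 6000 time units.  These
sizes are the package's validation protocol, not estimates of production
workloads; sharper comparisons simply need longer runs.

## Limitations

- Well-mixed populations only: no spatial or deme structure, no kin
  discrimination, no age structure, no environmental stochasticity.
- The slow-manifold reduction and stationary analytics are two-type;
  multi-type systems are handled by simulation (exact or SDE).
- No time-dependent Fokker–Planck solutions and no quasi-stationary
  distributions at `μ = 0`; the stationary machinery requires `μ > 0`.
- The diffusion-level results assume weak cost (`ε` small) and large `Ω`;
  at very small populations the exact simulator is the only trustworthy
  level of description.
- The multi-type SDE's independent-increment noise structure is validated
  against the exact process in the regimes the package uses it; exotic rate
  functions with strongly correlated birth/death channels would need their
  own validation.
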