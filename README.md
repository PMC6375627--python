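# demosoc — social evolution under demographic stochasticity

`demosoc` is a research toolkit for studying how randomness in individual
birth and death events (demographic stochasticity) biases the evolution of
indiscriminate social traits — altruism and spite — in well-mixed populations
of fluctuating size.  It is written for theoretical and microbial
evolutionary biologists who want to move between three levels of description
of the same system and check them against each other:

1. an **exact individual-based process** (continuous-time birth–death–mutation,
   simulated with the direct Gillespie method);
2. its **slow-timescale diffusion reduction** for the frequency `p` of social
   actors,

   ```
   dp = α(p) dt + √(σ²(p)) dW,
   α(p)  = μ(1 − 2p) − ε c(p) p(1 − p),
   σ²(p) = p(1 − p) T(p) / (Ω n(p)),
   ```

   where `n(p)` is the quasi-equilibrium population density on the ecological
   manifold `b = m`, `T(p) = b(p) + m(p) = 2b(p) = 2m(p)` is the population
   turnover, `Ω` the habitat size, `μ` the mutation rate and `εc` the cost of
   the social trait;
3. the **stationary distribution** `π(p) ∝ σ⁻²(p) exp(∫ 2α/σ² dp)` and an
   occupancy-based verdict: the social actor is *favoured* if
   `∫_{1/2}^{1} π(p) dp > 1/2`.

The scientific heart of the package is the ratio `T(p)/n(p)`: the frequency
process spends the most time where demographic noise is weakest, i.e. where
population size `n` is large *and* turnover `T` is slow.  Its derivative
splits as

```
d/dp [T/n] = (T/n) · ( −(dn/dp)/n + (dT/dp)/T ),
```

a population-**size** effect plus a **turnover** effect.  Social actions on
the death rate move both terms the same way (altruism always stochastically
favoured, spite disfavoured); actions on the birth rate set them against
each other, so either trait can win, an intermediate action level `ν*` can be
optimal, and a costly trait can even be favoured — a *selective reversal* —
when the habitat is small.  The package ships the model families realizing
all of these regimes, including the matched pair of altruism models with
identical deterministic dynamics but different turnover (only one of which
can reverse).

## Worked example

Death-rate altruism (`b = 3(1 − n)`, `m = 1 + νx₁/n`, `ν = −0.95`, `Ω = 900`,
`μ = 0.006`, cost-free):

```python
import demosoc as ds

model = ds.make_model("death_rate", {"beta": 3, "d": 1, "nu": -0.95},
                      omega=900, mu=0.006)
dist = ds.stationary_density(model)
report = ds.favourability(dist)
print(report.mass_above_half, report.favoured, report.shape)
# 0.5333  True  bell
print(dist.boundary_exponents)
# (2.6, 105.2)
```

The stationary occupancy puts 53.3% of its mass above `p = 1/2`: the altruist
is stochastically favoured.  The boundary exponents say why the density is
unimodal here: near `p = 1` the turnover `T` is tiny, so the effective
mutation supply `2μΩn/T` is huge and the mass accumulating at that boundary
is pushed just interior.  An exact-process occupancy histogram
(`ds.occupancy_ssa(...)`) reproduces this density to a few percent total
variation.

The optimal level of birth-rate altruism (`b = β + νx₁`,
`m = d + κ₁n + κ₂n²`, `{β, d, κ₁, κ₂} = {1, 0.5, 0.75, 0.01}`):

```python
res = ds.optimal_social_action("birth_altruism",
                               {"beta": 1, "d": 0.5, "kappa1": 0.75, "kappa2": 0.01})
print(res.nu_star_closed, res.nu_star_numeric, res.objective)
# 0.75  0.750000002  1.782843
```

The closed form `ν* = κ₁ − |β − 2d|/θ` with `θ = √(d/κ₂)` and an independent
numeric minimization of `T(1)/n(1)` agree: an intermediate action strength
minimizes demographic noise in a monomorphic population.

The same computations are available from the shell:

```bash
demosoc stationary --preset death_altruism --out altruism
demosoc optimal-nu --family birth_altruism --omega 250 \
    --param beta=1 --param d=0.5 --param kappa1=0.75 --param kappa2=0.01
demosoc scan-reversal --preset altruism_model2 --mu 0.02 \
    --omega-values 100,500,2000 --epsilon-values 0.003
demosoc list-models
```

Each run writes a tab-separated table plus a JSON summary stamped with the
configuration hash, and is byte-reproducible given the same config and seed.

## Layout

- `demosoc.models` — model families, parameter validation, trait ladders
- `demosoc.manifold` — quasi-equilibrium `n(p)`, turnover, diffusion
  coefficients, `T/n` decomposition
- `demosoc.stationary` — stationary densities (general integrator + closed
  forms), favourability and shape classification
- `demosoc.ssa` — exact Gillespie simulation, fixation probabilities,
  time-weighted occupancy histograms
- `demosoc.sde` — Euler–Maruyama integration of the frequency and multi-type
  density SDEs, noise-induced-drift diagnostics
- `demosoc.experiments` — optimal `ν*`, reversal scans, mutation sweeps, the
  mutation-fixation Markov chain, neutral invasion probabilities
- `demosoc.config` / `demosoc.runner` / `demosoc.cli` — strict YAML configs,
  presets, artifact writing, command-line interface

See `docs/methods.md` for the modelling assumptions, numerical choices and
known limitations.
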