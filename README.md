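# srdmsim

Individual-based simulation of **feminising sex-ratio-distorting microbes**
(SRDMs, e.g. *Wolbachia*-like endosymbionts) in arthropod host populations,
and of the extinction risk they create under environmental variation.

Maternally inherited microbes cannot pass through males, and many have
evolved to bias host broods toward daughters. `srdmsim` models the
feminising mechanism — infected offspring develop as females — and asks how
such infections interact with a changing environment to drive host
populations extinct. It is aimed at evolutionary ecologists and
epidemiological modellers who want a tested, reproducible implementation of
this class of host–endosymbiont model.

## The model

A population of adults evolves over non-overlapping generations, each a
breeding season of δ days (default 90). Every adult carries a fixed
phenotype P ∈ [0, 1]; each generation the environment sets an optimum
E ∈ [0, 1], either along a sine wave

    E_t = L + (U − L)/2 · (1 + sin(t / R)),

a fresh uniform draw on [L, U] (stochastic mode), or a constant. Daily
dynamics within a season:

- **Adult mortality.** Each adult dies with daily probability
  `D = (1 − 1/(1 + c·|P − E|)) · (1 − S)`, where c (default 0.2) sets the
  sensitivity to phenotype–environment mismatch and S ∈ [0, 0.5] is the
  survival benefit the microbe grants its (infected, hence female) carriers.
- **Mating.** Males quest for females; a female is located with daily
  probability `m = (β/δ) · r/(r + θ)`, with r = M/F the male:female ratio,
  β the lifetime matings a female averages when males are abundant
  (default 4) and θ a male dispersal parameter (larger θ, poorer dispersal).
  A female mates at most once per day; each brood has a single father.
- **Reproduction.** A mated female lays σ = 50 eggs. If she is infected,
  Binomial(σ, γ) of them inherit the microbe and develop as females;
  uninfected offspring are male or female with equal probability. Offspring
  inherit the midparent phenotype, except mutants (probability φ = 0.01)
  which draw a fresh Uniform(0, 1) phenotype.

After the season, the pooled juveniles J suffer one density-dependent cull
(death probability `d = J/(J + X)`, X = 500) and the survivors emerge as
the next generation's adults. A population is extinct when either sex falls
below one adult at emergence.

On top of the simulator, four analysis protocols mirror how this class of
model is interrogated:

- `ecological_experiment` — trajectory tables of abundance, mating rate and
  infection prevalence;
- `sensitivity_experiment` — Latin Hypercube sampling over (γ, S, θ), with a
  binomial GLM for extinction (Firth bias-reduced under separation) and an
  OLS model for mean prevalence;
- `mechanistic_experiment` — growth rate log N_{t+1} − log N_t against
  abundance and operational sex ratio (females per male) at γ = 0.9, with
  4th-degree polynomial smoothers;
- `evolutionary_experiment` — the rate of phenotypic evolution
  Σᵢ |P̄ᵢ − P̄ᵢ₊₁| across environment × transmission cells.

## Worked example

```python
from srdmsim import (SimulationParams, EnvironmentConfig,
                     run_simulation, evolutionary_rate)

params = SimulationParams(gamma=0.9, n_generations=50)   # defaults otherwise
env = EnvironmentConfig.from_scenario("high")            # E cycles 0.3–0.7
traj = run_simulation(params, env, rng=1)

print(f"extinct: {traj.extinct} (generation {traj.extinction_generation})")
print(traj.to_dataframe().head(6).round(3))
print("evolutionary rate:", round(evolutionary_rate(traj), 3))
```

prints

```
extinct: True (generation 45)
 generation     E  n_adults_start   osr  prevalence  matings_per_female  mean_phenotype
          0 0.500             500 0.931       0.036               0.502           0.514
          1 0.520             468 1.167       0.073               0.706           0.529
          2 0.540             436 1.096       0.069               0.974           0.517
          3 0.559             505 1.235       0.101               0.839           0.521
          4 0.578             474 1.301       0.148               0.787           0.519
          5 0.596             451 1.669       0.264               0.621           0.525
evolutionary rate: 0.157
```

Read: founding prevalence 10% climbs within a few generations (high
transmission, γ = 0.9), the operational sex ratio (females per male) drifts
upward as feminised broods accumulate, and in a highly variable environment
the combination of sex-ratio skew and phenotype–environment mismatch kills
the population at generation 45. The evolutionary rate is the summed
generation-to-generation movement of the mean phenotype as it chases E.

The same run from the shell:

```sh
srdmsim single-run --gamma 0.9 --env high --seed 1 --generations 50 --out demo
```

writes `demo/trajectory.csv` (one row per generation, as above) and
`demo/summary.csv`, each with a `#`-prefixed provenance header (package
version, config hash, seed, full canonical config). The other subcommands —
`ecological`, `sensitivity`, `mechanistic`, `evolutionary` — run the full
protocols with the same flags (`--env`, `--mode`, `--reps`, `--generations`,
`--seed`, `--out`, plus parameter overrides such as `--gamma`); re-running
with the same configuration and seed reproduces every table.

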