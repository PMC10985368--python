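# Methods

## Model overview

`srdmsim` is an individual-based model (IBM) of an arthropod host population
carrying a maternally inherited, feminising endosymbiont. The IBM runs on a
daily cycle inside breeding seasons of δ days; generations are
non-overlapping, so adults and juveniles never coexist and only adults are
alive during a season. All rates below weight Bernoulli/binomial draws for
each individual, so demographic stochasticity is intrinsic; environmental
stochasticity enters through the between-generation environment process.

### State

Each adult has a fixed phenotype P ∈ [0, 1], a sex, and an infection flag.
Infection is exclusively female: transmission is maternal and every infected
offspring develops as a female, so an infected male cannot exist (this is
enforced as a class invariant, not just a simulation outcome).

### Environment

One value E ∈ [0, 1] per generation, fixed for the whole season, doubles as
the environmental state and the optimal phenotype. Modes:

- **cyclical** — `E_t = L + (U − L)/2 · (1 + sin(t/R))` with t the
  generation index; E spans exactly [L, U]. R (default 10) controls the
  period (≈ 63 generations per full cycle), so a 50–100 generation run sees
  one to two slow swings.
- **stochastic** — E ~ Uniform(L, U) independently each generation.
- **constant** — E = U = L.

The named scenarios are symmetric around 0.5: constant (0.5, 0.5), moderate
(0.6, 0.4) and high (0.7, 0.3); "low" is accepted as an alias for constant.

### Daily cycle

1. Every adult dies with probability
   `D = (1 − 1/(1 + c·|P − E|))·(1 − S)`; c > 0 (default 0.2) scales the
   cost of phenotype–environment mismatch (maximum daily death
   c/(1+c) ≈ 0.167 at the default), and S ∈ [0, 0.5] is the microbe's
   survival benefit, applied only to infected individuals (S ≡ 0 for the
   uninfected). D multiplies the *death* probability by (1 − S), the
   simplest reading of a proportional survival benefit.
2. The daily encounter probability is `m = (β/δ)·r/(r + θ)` with r = M/F.
   m depends on the sexes only through their ratio, saturates at β/δ < 1
   (so a female in a male-rich population averages β lifetime matings) and
   falls as θ rises; θ is a proxy for (poor) male dispersal. Each living
   female mates with probability m, at most once per day; each mating's
   father is drawn uniformly from that day's living males, with no limit on
   male mating frequency.
3. Each mated female lays a brood of σ eggs at the end of the day. An
   infected mother transmits to Binomial(σ, γ) of them — all daughters;
   every uninfected offspring is male with probability 1/2. Offspring take
   the midparent phenotype except mutants (probability φ), which draw
   Uniform(0, 1).

At the end of the season all adults are removed; the pooled juveniles J
undergo one density-dependent cull, each dying with probability
`d = J/(J + X)`, and survivors emerge as the next generation's adults.
Expected survivors J·X/(J+X) < X, which regulates abundance below ≈ X
regardless of fecundity.

### Extinction

A population is extinct when, at adult emergence, either sex has fewer than
one adult (this also catches seasons that produced no surviving juveniles).
We deliberately do **not** declare extinction when one sex dies out
mid-season: that season's broods are already laid and still emerge, so a
cohort whose last male dies on day 80 after fathering thousands of eggs is
not biologically extinct. An earlier daily-check variant killed ~2–3% of
*uninfected* well-regulated populations in the high-variability scenario
purely through this bookkeeping (all ~200 males of a cohort occasionally die
before day 90 when mismatch mortality is ~0.04/day), which contradicts the
model's intended behaviour that uninfected populations never go extinct; the
emergence-time rule removes that artifact while leaving the
feminisation-driven extinction pathways (male scarcity → failed matings →
empty or single-sex cohorts) intact.

## Parameters

| Symbol | Meaning | Default | Range used |
|---|---|---|---|
| δ | breeding season length (days) | 90 | fixed |
| c | selection coefficient of mismatch mortality (dimensionless) | 0.2 | fixed |
| S | survival benefit of infection (proportion) | 0 | 0–0.5 |
| θ | male dispersal parameter (dimensionless) | 1.5 | 0.05–5 |
| β | lifetime matings per female under male excess | 4 | fixed (δ > β) |
| σ | brood size (eggs per mating) | 50 | fixed |
| γ | vertical transmission probability | 0.9 | 0.5–1 sampled; 0, 0.2–0.8 in controls |
| φ | mutation probability per offspring | 0.01 | fixed |
| X | juvenile competition parameter (juveniles) | 500 | fixed |
| U, L | environment limits | scenario | 0.5/0.5, 0.6/0.4, 0.7/0.3 |
| R | environmental wave-frequency constant | 10 | fixed |

Initialisation (not constrained by the model definition, config-exposed):
500 founding adults (= X), fair-coin sexes, phenotypes Uniform(0, 1)
("uniform" mode; "matched" pins all phenotypes to the first season's E for
mortality-free controlled tests), and 10% of founding females infected.
Uniform phenotypes supply the standing variation the evolutionary analysis
consumes; founding prevalence 0.1 lets invasion or loss of the microbe be an
outcome rather than an assumption. Uninfected controls set γ = 0 and
founding prevalence 0.

## Numerical design

- **Vectorised season.** The population is stored as parallel numpy arrays.
  Daily survival draws are realised by sampling each adult's lifetime once
  per season from the geometric distribution implied by its daily D
  (identical in distribution to day-by-day Bernoulli draws); daily mating
  counts are Binomial(F_t, m_t) with the mated females a uniform random
  subset of that day's survivors — again exactly the distribution of
  per-female Bernoulli draws. Broods are generated in one batch at season
  end. A 50-generation run takes ~1–3 ms per generation.
- **Randomness and reproducibility.** One `numpy.random.Generator` per
  replicate; replicate i (1-based) of a protocol is seeded `base_seed + i`,
  the Latin Hypercube draw uses `base_seed`, and multi-cell experiments
  offset cells by 100 000. Every output table records its seeds.
  Bit-reproducibility is guaranteed within this implementation only.
- **Latin Hypercube sampling** uses `scipy.stats.qmc.LatinHypercube`
  (one point per equal stratum per dimension); a degenerate range
  (lo == hi) is treated as a held-fixed parameter.
- **Extinction GLM.** `statsmodels` binomial GLM with logit link. Because γ
  separates extinction almost perfectly in the constant scenario, diverging
  maximum-likelihood fits are detected (non-finite or absurd standard
  errors) and refitted with a hand-implemented Firth bias-reduced logistic
  regression (Jeffreys-prior penalised score with hat-diagonal correction),
  which keeps estimates finite under complete separation and is flagged in
  the fit summary. Prediction curves sweep one parameter over its sampled
  range with the others at range midpoints.
- **Growth-rate smoothers.** Growth log N_{t+1} − log N_t (natural log;
  the base only rescales) is smoothed against log N and against the
  operational sex ratio with a global 4th-degree least-squares polynomial,
  fitted on a standardised abscissa. Trend questions are answered with the
  *average* slope of the fitted curve over a window,
  (f(b) − f(a))/(b − a), a linear functional of the coefficients whose
  standard error follows from the OLS covariance. For the Allee-effect
  check (is growth rising with N at low abundance?) the window is the lower
  quartile of observed N and the requirement is a non-positive 99% upper
  bound. We use the average rather than the pointwise derivative because a
  global quartic oscillates near sparse data boundaries — at e.g. N < 200,
  where a handful of points steer the curve, pointwise slopes of either
  sign appear whose binned raw means are flat or decreasing; the windowed
  average measures the trend the hypothesis is actually about. Pairs
  adjacent to an extinction (N → 0) are excluded from the growth table and
  counted.
- **Prevalence model.** Replicate mean prevalence (averaged over the
  generations actually realised before extinction) regressed on γ, S, θ by
  OLS.
- **Evolutionary rate.** Σᵢ |P̄ᵢ − P̄ᵢ₊₁| over a trajectory's recorded
  generations. Replicates that go extinct before completing the run are
  excluded from cell means and reported in an `n_excluded` column rather
  than silently averaged.
- **Censusing.** All per-generation observables (N, sex counts, prevalence,
  OSR = females/male, mean phenotype) are measured at adult emergence,
  before any mortality; the mating rate is matings per female alive at
  emergence.

## What the simulations do and do not emulate

The generator produces the study conditions themselves — there is no
external data. It captures demographic stochasticity, environmentally driven
mortality, sex-ratio dynamics and vertical transmission in a single
well-mixed population. It does not capture spatial structure or migration,
overlapping generations, within-season environmental change,
temperature-sensitive transmission, horizontal transmission, male-killing or
parthenogenesis-inducing mechanisms, or any genetics beyond a single
blending trait with rare uniform mutation. Passing tests therefore support
the internal logic of the feminiser–environment–extinction mechanism, not
quantitative predictions for any real arthropod population.

## Problem sizes

The test suite and acceptance script use the protocols' standard sizes:
100 replicates per cell for the sensitivity (50 generations), mechanistic
(100 generations) and evolutionary (50 generations) protocols, and 20
replicates × 100 generations per scenario for the ecological protocol. The
full suite runs in a few minutes on one CPU; the acceptance script in about
a minute.

## Known limitations

- Midparent inheritance halves trait variance each generation; with φ = 0.01
  as the only variance source, long-run adaptability is mutation-limited, so
  populations track slow environmental swings with a lag. This is inherent
  to the blending-inheritance formulation.
- The Firth fallback reports Wald standard errors from the penalised
  information matrix; under heavy separation these are approximate and the
  fit summary flags the replicate table as separated.
- The 4th-degree polynomial is a global smoother: its pointwise behaviour
  outside dense data regions should not be interpreted (see the average-slope
  statistic above).
- OSR is reported as females per male and is infinite for an all-female
  cohort; such cohorts only occur at the extinction boundary and never enter
  the growth tables.
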