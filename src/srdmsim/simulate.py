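"""Daily/seasonal individual-based dynamics and per-generation observables.

A simulation advances in non-overlapping generations.  Each generation is a
breeding season of ``delta`` days during which only adults exist:

1. at the start of each day every adult survives with probability
   ``1 - D_i`` (phenotype-environment mismatch mortality);
2. the daily per-female encounter probability ``m`` is computed from the
   living sex ratio (mating stops for the rest of the season once either
   sex has no living adult);
3. each living female independently mates with probability ``m`` (at most
   once per day); each mating assigns a father drawn uniformly from the
   males alive that day (males may father any number of broods);
4. every mated female lays a brood of ``sigma`` eggs at the end of the day.

Offspring develop after the season: the pooled juveniles suffer one
density-dependent cull (each dies with probability ``J / (J + X)``) and the
survivors emerge as the next season's adults.

Extinction (either sex below one adult) is assessed at adult emergence,
before each season: losing the last male or female mid-season ends mating
but not the population, because that season's already-laid broods still
emerge.  A season producing no surviving juveniles, or survivors of only
one sex, is therefore caught at the next season's start.

The population is stored as parallel numpy arrays (phenotype, sex,
infection) rather than as a list of objects; daily survival is realised by
drawing each adult's geometric lifetime up front, which is distributionally
identical to per-day Bernoulli draws and lets the season run vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    FEMALE,
    MALE,
    EnvironmentConfig,
    Individual,
    SimulationParams,
    adult_death_prob,
    environment_value,
)

__all__ = [
    "Population",
    "SeasonRecord",
    "Trajectory",
    "initialize_population",
    "run_season",
    "run_simulation",
]


class Population:
    """Adult cohort as parallel arrays: phenotype, male flag, infected flag."""

    __slots__ = ("phenotype", "male", "infected")

    def __init__(self, phenotype: np.ndarray, male: np.ndarray, infected: np.ndarray):
        self.phenotype = np.asarray(phenotype, dtype=float)
        self.male = np.asarray(male, dtype=bool)
        self.infected = np.asarray(infected, dtype=bool)
        if not (self.phenotype.shape == self.male.shape == self.infected.shape):
            raise ValueError("population arrays must have equal length")
        if np.any(self.male & self.infected):
            raise ValueError("infected males are impossible under feminisation")

    @classmethod
    def empty(cls) -> "Population":
        z = np.empty(0)
        return cls(z, z.astype(bool), z.astype(bool))

    @property
    def size(self) -> int:
        return self.phenotype.size

    @property
    def n_males(self) -> int:
        return int(self.male.sum())

    @property
    def n_females(self) -> int:
        return self.size - self.n_males

    @property
    def n_infected(self) -> int:
        return int(self.infected.sum())

    def __len__(self) -> int:
        return self.size

    def __iter__(self) -> Iterator[Individual]:
        for p, m, i in zip(self.phenotype, self.male, self.infected):
            yield Individual(float(p), MALE if m else FEMALE, bool(i))


@dataclass(frozen=True)
class SeasonRecord:
    """Observables for one generation, censused at adult emergence."""

    generation: int
    E: float
    n_adults_start: int
    n_males_start: int
    n_females_start: int
    n_infected_start: int
    prevalence: float
    osr: float  # operational sex ratio, females per male
    matings: int
    matings_per_female: float
    mean_phenotype: float
    n_juveniles: int


@dataclass
class Trajectory:
    """Ordered season records plus the extinction outcome of one run."""

    records: list[SeasonRecord] = field(default_factory=list)
    extinct: bool = False
    extinction_generation: Optional[int] = None

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_adults(self) -> np.ndarray:
        return np.array([r.n_adults_start for r in self.records], dtype=float)

    @property
    def prevalence(self) -> np.ndarray:
        return np.array([r.prevalence for r in self.records], dtype=float)

    @property
    def mean_phenotype(self) -> np.ndarray:
        return np.array([r.mean_phenotype for r in self.records], dtype=float)

    @property
    def osr(self) -> np.ndarray:
        return np.array([r.osr for r in self.records], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        """One row per generation; columns are the SeasonRecord fields."""
        df = pd.DataFrame([vars(r) for r in self.records])
        if df.empty:
            df = pd.DataFrame(
                columns=[f.name for f in SeasonRecord.__dataclass_fields__.values()]
            )
        return df


def initialize_population(
    params: SimulationParams,
    rng: np.random.Generator,
    env_value: Optional[float] = None,
) -> Population:
    """Found the initial adult cohort.

    Sexes are assigned by a fair coin; a fraction ``init_prevalence`` of the
    founding females carries the microbe.  Phenotypes are Uniform(0, 1) in
    ``uniform`` mode (standing variation for evolution experiments) or all
    equal to the first season's environment in ``matched`` mode (controlled,
    mortality-free baselines).
    """
    n = params.init_size
    if n < 2:
        raise ValueError("init_size must be >= 2")
    male = rng.random(n) < 0.5
    if params.init_phenotype_mode == "matched":
        e0 = 0.5 if env_value is None else float(env_value)
        phen = np.full(n, e0)
    else:
        phen = rng.random(n)
    infected = np.zeros(n, dtype=bool)
    fem = np.flatnonzero(~male)
    if params.init_prevalence > 0 and fem.size:
        infected[fem] = rng.random(fem.size) < params.init_prevalence
    return Population(phen, male, infected)


def _survival_counts(alive_days: np.ndarray, delta: int) -> np.ndarray:
    """Per-day living counts: entry d-1 is the number alive on day d (1..delta)."""
    cnt = np.bincount(alive_days, minlength=delta + 1)
    surv = np.cumsum(cnt[::-1])[::-1]  # surv[v] = #(alive_days >= v)
    return surv[1:]


def run_season(
    adults: Population,
    E: float,
    params: SimulationParams,
    rng: np.random.Generator,
    generation: int = 0,
) -> tuple[Population, SeasonRecord]:
    """Run one breeding season; return (next cohort, season record).

    The record holds emergence-time observables.  Mating happens only on
    days with at least one living adult of each sex; the next cohort is the
    season's pooled brood after the single density-dependent cull and may be
    empty or single-sex, which the caller treats as extinction at the next
    emergence.
    """
    n0 = adults.size
    M0 = adults.n_males
    F0 = n0 - M0
    n_inf = adults.n_infected
    delta = params.delta

    # Each adult's count of days alive for mating: deaths strike at the start
    # of a day, so an adult whose first failed survival draw is day T
    # participates on days 1..T-1.  Geometric lifetimes == daily Bernoulli.
    S_eff = np.where(adults.infected, params.S, 0.0)
    D = adult_death_prob(adults.phenotype, np.full(n0, E), params.c, S_eff)
    D = np.atleast_1d(np.asarray(D, dtype=float))
    alive_days = np.full(n0, delta, dtype=np.int64)
    mortal = D > 0
    if np.any(mortal):
        alive_days[mortal] = np.minimum(rng.geometric(D[mortal]) - 1, delta)

    male = adults.male
    M_t = _survival_counts(alive_days[male], delta)
    F_t = _survival_counts(alive_days[~male], delta)

    # encounters need both sexes alive; counts only fall, so valid days are a prefix
    valid = (M_t >= 1) & (F_t >= 1)

    matings = 0
    mothers_p: list[np.ndarray] = []
    mothers_i: list[np.ndarray] = []
    fathers_p: list[np.ndarray] = []
    if np.any(valid):
        Md = M_t.astype(float)
        Fd = np.where(valid, F_t, 1).astype(float)
        r = Md / Fd
        m = np.where(valid, (params.beta / delta) * r / (r + params.theta), 0.0)
        k = rng.binomial(F_t, m)
        matings = int(k.sum())
        if matings:
            fem_idx = np.flatnonzero(~male)
            mal_idx = np.flatnonzero(male)
            fem_sorted = fem_idx[np.argsort(-alive_days[fem_idx], kind="stable")]
            mal_sorted = mal_idx[np.argsort(-alive_days[mal_idx], kind="stable")]
            phen = adults.phenotype
            inf = adults.infected
            for di in np.flatnonzero(k):
                kk = int(k[di])
                # females alive on day di+1 are a prefix of the sorted order
                moms = fem_sorted[rng.choice(F_t[di], size=kk, replace=False)]
                dads = mal_sorted[rng.integers(0, M_t[di], size=kk)]
                mothers_p.append(phen[moms])
                mothers_i.append(inf[moms])
                fathers_p.append(phen[dads])

    next_pop, n_juv = _spawn_juveniles(
        mothers_p, mothers_i, fathers_p, params, rng
    )

    record = SeasonRecord(
        generation=generation,
        E=float(E),
        n_adults_start=n0,
        n_males_start=M0,
        n_females_start=F0,
        n_infected_start=n_inf,
        prevalence=n_inf / n0 if n0 else float("nan"),
        osr=F0 / M0 if M0 else float("inf"),
        matings=matings,
        matings_per_female=matings / F0 if F0 else float("nan"),
        mean_phenotype=float(adults.phenotype.mean()) if n0 else float("nan"),
        n_juveniles=n_juv,
    )
    return next_pop, record


def _spawn_juveniles(
    mothers_p: Sequence[np.ndarray],
    mothers_i: Sequence[np.ndarray],
    fathers_p: Sequence[np.ndarray],
    params: SimulationParams,
    rng: np.random.Generator,
) -> tuple[Population, int]:
    """Lay all broods, then apply the single density-dependent juvenile cull."""
    if not mothers_p:
        return Population.empty(), 0
    mp = np.concatenate(mothers_p)
    mi = np.concatenate(mothers_i)
    fp = np.concatenate(fathers_p)
    nb = mp.size
    sigma = params.sigma

    k_inf = np.where(mi, rng.binomial(sigma, params.gamma, size=nb), 0)
    n_male = rng.binomial(sigma - k_inf, 0.5)

    total = nb * sigma
    brood = np.repeat(np.arange(nb), sigma)
    pos = np.tile(np.arange(sigma), nb)
    j_infected = pos < k_inf[brood]
    j_male = pos >= (sigma - n_male)[brood]  # disjoint from infected slots

    j_phen = (0.5 * (mp + fp))[brood]
    mutant = rng.random(total) < params.phi
    n_mut = int(mutant.sum())
    if n_mut:
        j_phen = j_phen.copy()
        j_phen[mutant] = rng.random(n_mut)

    d = total / (total + params.X)
    keep = rng.random(total) >= d
    return Population(j_phen[keep], j_male[keep], j_infected[keep]), total


def run_simulation(
    params: SimulationParams,
    env_cfg: EnvironmentConfig,
    rng: np.random.Generator | int,
) -> Trajectory:
    """Run ``n_generations`` seasons (or until extinction); deterministic per seed.

    Extinction is assessed at each adult emergence: the first generation
    whose cohort lacks a living male or female is recorded as the extinction
    generation and contributes no season record.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    traj = Trajectory()
    pop: Optional[Population] = None
    for t in range(params.n_generations):
        E = environment_value(t, env_cfg, rng)
        if pop is None:
            pop = initialize_population(params, rng, env_value=E)
        if pop.n_males < 1 or pop.n_females < 1:
            traj.extinct = True
            traj.extinction_generation = t
            break
        pop, record = run_season(pop, E, params, rng, generation=t)
        traj.records.append(record)
    return traj
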