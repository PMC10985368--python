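"""Domain types and elementary stochastic rates for a feminiser epidemic model.

The model describes an arthropod host population infected by a maternally
inherited, feminising endosymbiont (e.g. a *Wolbachia*-like microbe).  Each
adult carries a fixed phenotype ``P`` in [0, 1]; the environment supplies a
per-generation optimum ``E`` on the same scale, and daily adult mortality
grows with the phenotype-environment mismatch ``|P - E|``.  Infected mothers
transmit the microbe vertically with probability ``gamma``; infected
offspring develop as females, which is what skews the population sex ratio.

Everything in this module is a pure function of its arguments (randomness is
injected through a :class:`numpy.random.Generator`), so each rate can be
tested against closed-form values in isolation.  The daily/seasonal loop
that composes them lives in :mod:`srdmsim.simulate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "Individual",
    "SimulationParams",
    "EnvironmentConfig",
    "BroodComposition",
    "SCENARIOS",
    "environment_value",
    "adult_death_prob",
    "mate_encounter_prob",
    "juvenile_death_prob",
    "brood_composition",
    "offspring_phenotype",
]

MALE = "male"
FEMALE = "female"

#: Named environmental-variability scenarios as (upper, lower) limits of E.
#: ``low`` is an alias for ``constant`` (some analyses label the scenarios
#: low / moderate / high rather than constant / moderate / high).
SCENARIOS: dict[str, tuple[float, float]] = {
    "constant": (0.5, 0.5),
    "low": (0.5, 0.5),
    "moderate": (0.6, 0.4),
    "high": (0.7, 0.3),
}


@dataclass(frozen=True)
class Individual:
    """One adult host: fixed phenotype, sex, and infection status.

    Infection is maternally inherited and feminising, so an infected
    individual is female by construction; constructing an infected male
    raises ``ValueError``.
    """

    phenotype: float
    sex: str
    infected: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.phenotype <= 1.0:
            raise ValueError(f"phenotype must lie in [0, 1], got {self.phenotype}")
        if self.sex not in (MALE, FEMALE):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.infected and self.sex != FEMALE:
            raise ValueError("infected individuals are female (feminising microbe)")


@dataclass(frozen=True)
class SimulationParams:
    """Full parameterisation of one simulation.

    Defaults are the model's standard values: a 90-day breeding season,
    selection coefficient ``c = 0.2``, up to ``beta = 4`` lifetime matings
    per female when males are abundant, broods of ``sigma = 50`` eggs,
    transmission ``gamma = 0.9``, mutation rate ``phi = 0.01`` and juvenile
    competition parameter ``X = 500``.

    The ``init_*`` fields control how the founding cohort is built (size,
    fraction of founding females infected, and whether founder phenotypes
    are drawn uniformly on [0, 1] or matched exactly to the first season's
    environment for controlled experiments).
    """

    delta: int = 90
    c: float = 0.2
    S: float = 0.0
    theta: float = 1.5
    beta: float = 4.0
    sigma: int = 50
    gamma: float = 0.9
    phi: float = 0.01
    X: float = 500.0
    n_generations: int = 50
    init_size: int = 500
    init_prevalence: float = 0.1
    init_phenotype_mode: str = "uniform"

    def __post_init__(self) -> None:
        if self.delta < 1:
            raise ValueError("delta (season length, days) must be >= 1")
        if not self.delta > self.beta:
            raise ValueError(
                "delta must exceed beta so the daily encounter probability stays below 1"
            )
        if self.c <= 0:
            raise ValueError("c (selection coefficient) must be > 0")
        if not 0.0 <= self.S <= 0.5:
            raise ValueError(f"S must lie in [0, 0.5], got {self.S}")
        if self.theta <= 0:
            raise ValueError("theta (male dispersal parameter) must be > 0")
        if self.sigma < 1:
            raise ValueError("sigma (brood size) must be >= 1")
        for name in ("gamma", "phi", "init_prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.X <= 0:
            raise ValueError("X (juvenile competition parameter) must be > 0")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        if self.init_size < 2:
            raise ValueError("init_size must be >= 2 (need both sexes possible)")
        if self.init_phenotype_mode not in ("uniform", "matched"):
            raise ValueError("init_phenotype_mode must be 'uniform' or 'matched'")


@dataclass(frozen=True)
class EnvironmentConfig:
    """Between-generation environment process for the optimum E.

    ``cyclical`` mode follows a sine wave between the lower and upper limits
    ``L`` and ``U``; ``stochastic`` mode draws a fresh uniform value on
    [L, U] each generation; ``constant`` holds E at U (= L).  ``R`` sets the
    period of the cyclical wave (larger R, slower cycles).
    """

    mode: str = "cyclical"
    U: float = 0.5
    L: float = 0.5
    R: float = 10.0

    def __post_init__(self) -> None:
        if self.mode not in ("cyclical", "stochastic", "constant"):
            raise ValueError(
                f"mode must be 'cyclical', 'stochastic' or 'constant', got {self.mode!r}"
            )
        if not (0.0 <= self.L <= self.U <= 1.0):
            raise ValueError("environment limits must satisfy 0 <= L <= U <= 1")
        if self.R <= 0:
            raise ValueError("R (wave-frequency constant) must be > 0")

    @classmethod
    def from_scenario(cls, scenario: str, mode: str = "cyclical", R: float = 10.0) -> "EnvironmentConfig":
        """Build the named variability scenario (constant/low, moderate, high)."""
        try:
            U, L = SCENARIOS[scenario]
        except KeyError:
            raise ValueError(
                f"unknown scenario {scenario!r}; expected one of {sorted(SCENARIOS)}"
            ) from None
        if U == L and mode == "cyclical":
            mode = "constant"
        return cls(mode=mode, U=U, L=L, R=R)


@dataclass(frozen=True)
class BroodComposition:
    """Counts of infected females, uninfected females and males in one brood."""

    n_infected_females: int
    n_uninfected_females: int
    n_males: int

    def __post_init__(self) -> None:
        if min(self.n_infected_females, self.n_uninfected_females, self.n_males) < 0:
            raise ValueError("brood counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_infected_females + self.n_uninfected_females + self.n_males


def environment_value(
    t: int, cfg: EnvironmentConfig, rng: Optional[np.random.Generator] = None
) -> float:
    """Environmental optimum E for generation ``t``.

    Cyclical: ``E_t = L + (U - L)/2 * (1 + sin(t / R))``, so E spans exactly
    [L, U].  Stochastic: a fresh Uniform(L, U) draw (``rng`` required).
    Constant: U (= L).  E is drawn once per generation and held fixed over
    the whole breeding season.
    """
    if t < 0:
        raise ValueError("generation index t must be >= 0")
    if cfg.mode == "constant":
        return cfg.U
    if cfg.mode == "cyclical":
        return cfg.L + 0.5 * (cfg.U - cfg.L) * (1.0 + np.sin(t / cfg.R))
    if cfg.mode == "stochastic":
        if rng is None:
            raise ValueError("stochastic environment mode needs an rng")
        return float(rng.uniform(cfg.L, cfg.U))
    raise ValueError(f"invalid environment mode {cfg.mode!r}")  # pragma: no cover


def adult_death_prob(P, E, c: float, S=0.0):
    """Daily adult death probability from phenotype-environment mismatch.

    ``D = (1 - 1 / (1 + c * |P - E|)) * (1 - S)``.

    ``c`` sets how steeply mortality rises with the mismatch ``|P - E|``;
    ``S`` is the proportional survival benefit of carrying the microbe and
    must be 0 for uninfected individuals (the caller enforces that).  D is 0
    exactly when P = E and is bounded above by ``c / (1 + c)``.

    Accepts scalars or arrays (broadcasting elementwise).
    """
    P = np.asarray(P, dtype=float)
    E = np.asarray(E, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(P < 0) or np.any(P > 1):
        raise ValueError("phenotype P must lie in [0, 1]")
    if np.any(E < 0) or np.any(E > 1):
        raise ValueError("environment E must lie in [0, 1]")
    if c <= 0:
        raise ValueError("c must be > 0")
    if np.any(S < 0) or np.any(S > 0.5):
        raise ValueError("S must lie in [0, 0.5]")
    mismatch = np.abs(P - E)
    D = (1.0 - 1.0 / (1.0 + c * mismatch)) * (1.0 - S)
    return D if D.ndim else float(D)


def mate_encounter_prob(M: int, F: int, theta: float, beta: float, delta: int) -> float:
    """Daily probability that a given female is located by a questing male.

    With sex ratio ``r = M / F``: ``m = (beta / delta) * r / (r + theta)``.

    ``m`` depends on males only through the male:female ratio, saturates at
    ``beta / delta`` when males are in excess (so a female averages ``beta``
    lifetime matings), and shrinks as ``theta`` grows (poorer male
    dispersal).  Since ``delta > beta``, ``m < 1`` always.
    """
    if F < 1:
        raise ValueError(
            "mate_encounter_prob called with F < 1; the population is already "
            "extinct and the caller should have stopped the simulation"
        )
    if M < 0:
        raise ValueError("male count M must be >= 0")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    if not delta > beta:
        raise ValueError("delta must exceed beta")
    r = M / F
    return (beta / delta) * r / (r + theta)


def juvenile_death_prob(J: float, X: float) -> float:
    """Density-dependent juvenile death probability ``d = J / (J + X)``.

    Hyperbolic in the juvenile count J: competition for developmental
    resources intensifies with crowding.  Independent of the environment E.
    """
    if J < 0:
        raise ValueError("juvenile count J must be >= 0")
    if X <= 0:
        raise ValueError("X must be > 0")
    return J / (J + X)


def brood_composition(
    mother_infected: bool, sigma: int, gamma: float, rng: np.random.Generator
) -> BroodComposition:
    """Sex and infection make-up of one brood of ``sigma`` offspring.

    An infected mother transmits to ``k ~ Binomial(sigma, gamma)`` of her
    offspring; all infected offspring are female.  Uninfected offspring
    (every offspring of an uninfected mother) are male with probability 1/2.
    """
    if sigma < 1:
        raise ValueError("sigma must be >= 1")
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    k = int(rng.binomial(sigma, gamma)) if mother_infected else 0
    n_males = int(rng.binomial(sigma - k, 0.5))
    return BroodComposition(
        n_infected_females=k,
        n_uninfected_females=sigma - k - n_males,
        n_males=n_males,
    )


def offspring_phenotype(
    P_mother: float, P_father: float, phi: float, rng: np.random.Generator
) -> float:
    """Phenotype of one offspring: midparent value, or uniform if a mutant.

    With probability ``1 - phi`` the offspring inherits the mean of its
    parents' phenotypes; with probability ``phi`` it is a mutant with a
    fresh Uniform(0, 1) phenotype.
    """
    if not (0.0 <= P_mother <= 1.0 and 0.0 <= P_father <= 1.0):
        raise ValueError("parent phenotypes must lie in [0, 1]")
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must lie in [0, 1]")
    if rng.random() < phi:
        return float(rng.random())
    return 0.5 * (P_mother + P_father)
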