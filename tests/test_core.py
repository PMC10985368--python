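"""Unit and property tests for the elementary rate functions."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from srdmsim import (
    BroodComposition,
    EnvironmentConfig,
    Individual,
    SimulationParams,
    adult_death_prob,
    brood_composition,
    environment_value,
    juvenile_death_prob,
    mate_encounter_prob,
    offspring_phenotype,
)

unit = st.floats(0.0, 1.0, allow_nan=False)


class TestIndividual:
    def test_infected_implies_female(self):
        with pytest.raises(ValueError):
            Individual(phenotype=0.5, sex="male", infected=True)
        assert Individual(0.5, "female", True).infected

    def test_phenotype_bounds(self):
        with pytest.raises(ValueError):
            Individual(phenotype=1.2, sex="female")


class TestEnvironment:
    def test_constant_mode_returns_midpoint(self):
        cfg = EnvironmentConfig(mode="constant", U=0.5, L=0.5)
        assert environment_value(17, cfg) == 0.5

    def test_cyclical_spans_exactly_the_limits(self):
        cfg = EnvironmentConfig(mode="cyclical", U=0.7, L=0.3, R=10.0)
        # choose t where sin(t/R) is at its extrema
        t_up = int(round(np.pi / 2 * 10))  # sin ~ +1
        ts = np.arange(0, 400)
        es = np.array([environment_value(t, cfg) for t in ts])
        assert es.min() >= 0.3 - 1e-12 and es.max() <= 0.7 + 1e-12
        assert es.max() == pytest.approx(0.7, abs=1e-3)
        assert es.min() == pytest.approx(0.3, abs=1e-3)
        # analytic check of the wave formula itself
        assert environment_value(t_up, cfg) == pytest.approx(
            0.3 + 0.2 * (1 + np.sin(t_up / 10.0))
        )

    def test_stochastic_draws_are_uniform_on_the_band(self, rng):
        cfg = EnvironmentConfig(mode="stochastic", U=0.7, L=0.3)
        draws = np.array([environment_value(t, cfg, rng) for t in range(10_000)])
        assert draws.min() >= 0.3 and draws.max() <= 0.7
        assert draws.mean() == pytest.approx(0.5, abs=0.005)

    def test_scenario_presets(self):
        assert EnvironmentConfig.from_scenario("high").U == 0.7
        assert EnvironmentConfig.from_scenario("moderate").L == 0.4
        # 'low' aliases the constant scenario
        assert EnvironmentConfig.from_scenario("low").mode == "constant"
        with pytest.raises(ValueError):
            EnvironmentConfig.from_scenario("extreme")


class TestAdultDeath:
    @pytest.mark.parametrize(
        "P,E,c,S,expected",
        [
            (0.5, 0.5, 0.2, 0.0, 0.0),  # perfect match
            (1.0, 0.0, 0.2, 0.0, 1.0 - 1.0 / 1.2),  # maximal mismatch
            (1.0, 0.0, 0.2, 0.5, (1.0 - 1.0 / 1.2) * 0.5),  # benefit halves death
        ],
    )
    def test_canonical_values(self, P, E, c, S, expected):
        assert adult_death_prob(P, E, c, S) == pytest.approx(expected, abs=1e-6)

    @given(P=unit, E=unit, S=st.floats(0.0, 0.5))
    def test_symmetric_probability_zero_iff_match(self, P, E, S):
        d1 = adult_death_prob(P, E, 0.2, S)
        d2 = adult_death_prob(E, P, 0.2, S)
        assert d1 == pytest.approx(d2)
        assert 0.0 <= d1 < 1.0
        if S < 0.5:
            if P == E:
                assert d1 == 0.0
            if d1 == 0.0:  # converse, up to float underflow of c*|P-E|
                assert abs(P - E) < 1e-15

    @given(E=unit, d1=st.floats(0.0, 1.0), d2=st.floats(0.0, 1.0))
    def test_monotone_in_mismatch_and_benefit(self, E, d1, d2):
        lo, hi = sorted([d1, d2])
        P_lo = min(E + lo, 1.0) if E <= 0.5 else max(E - lo, 0.0)
        P_hi = min(E + hi, 1.0) if E <= 0.5 else max(E - hi, 0.0)
        assert adult_death_prob(P_lo, E, 0.2) <= adult_death_prob(P_hi, E, 0.2) + 1e-15
        assert adult_death_prob(P_hi, E, 0.2, 0.3) <= adult_death_prob(P_hi, E, 0.2, 0.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            adult_death_prob(1.5, 0.5, 0.2)
        with pytest.raises(ValueError):
            adult_death_prob(0.5, 0.5, -1.0)
        with pytest.raises(ValueError):
            adult_death_prob(0.5, 0.5, 0.2, 0.9)


class TestMateEncounter:
    def test_no_males_means_no_encounters(self):
        assert mate_encounter_prob(0, 50, theta=1.5, beta=4, delta=90) == 0.0

    def test_even_sex_ratio_value(self):
        m = mate_encounter_prob(100, 100, theta=1.5, beta=4, delta=90)
        assert m == pytest.approx((4 / 90) * (1 / 2.5), abs=1e-6)

    def test_saturates_at_beta_over_delta_in_male_excess(self):
        m = mate_encounter_prob(10**9, 1, theta=1.5, beta=4, delta=90)
        assert m == pytest.approx(4 / 90, rel=1e-6)

    @given(
        M=st.integers(0, 10_000),
        F=st.integers(1, 10_000),
        k=st.integers(1, 50),
    )
    def test_depends_only_on_the_sex_ratio(self, M, F, k):
        a = mate_encounter_prob(M, F, 1.5, 4, 90)
        b = mate_encounter_prob(k * M, k * F, 1.5, 4, 90)
        assert a == pytest.approx(b)
        assert 0.0 <= a < 4 / 90 + 1e-12

    @given(M=st.integers(1, 1000), F=st.integers(1, 1000))
    def test_decreasing_in_theta(self, M, F):
        assert mate_encounter_prob(M, F, 0.5, 4, 90) >= mate_encounter_prob(
            M, F, 2.0, 4, 90
        )

    def test_no_females_is_a_contract_violation(self):
        with pytest.raises(ValueError, match="extinct"):
            mate_encounter_prob(10, 0, 1.5, 4, 90)


class TestJuvenileDeath:
    @pytest.mark.parametrize(
        "J,X,expected", [(0, 500, 0.0), (500, 500, 0.5), (1500, 500, 0.75)]
    )
    def test_hyperbolic_values(self, J, X, expected):
        assert juvenile_death_prob(J, X) == pytest.approx(expected)

    @given(J=st.integers(0, 10**6))
    def test_bounded_and_increasing(self, J):
        d = juvenile_death_prob(J, 500)
        assert 0.0 <= d < 1.0
        assert juvenile_death_prob(J + 1, 500) >= d

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            juvenile_death_prob(-1, 500)


class TestBroodComposition:
    def test_certain_transmission_gives_all_infected_females(self, rng):
        b = brood_composition(True, sigma=50, gamma=1.0, rng=rng)
        assert b == BroodComposition(50, 0, 0)

    def test_uninfected_mother_never_transmits_and_sexes_fairly(self, rng):
        males = 0
        for _ in range(2_000):
            b = brood_composition(False, sigma=50, gamma=0.9, rng=rng)
            assert b.n_infected_females == 0
            assert b.total == 50
            males += b.n_males
        assert males / (2_000 * 50) == pytest.approx(0.5, abs=0.01)

    def test_infected_counts_follow_binomial_moments(self, rng):
        ks = np.array(
            [
                brood_composition(True, 50, 0.9, rng).n_infected_females
                for _ in range(10_000)
            ]
        )
        assert ks.mean() == pytest.approx(45.0, abs=0.15)
        assert ks.var() == pytest.approx(4.5, rel=0.15)

    @given(sigma=st.integers(1, 100), gamma=unit, infected=st.booleans())
    def test_counts_conserved(self, sigma, gamma, infected):
        rng = np.random.default_rng(1234)
        b = brood_composition(infected, sigma, gamma, rng)
        assert b.total == sigma
        assert min(b.n_infected_females, b.n_uninfected_females, b.n_males) >= 0


class TestOffspringPhenotype:
    def test_midparent_without_mutation(self, rng):
        assert offspring_phenotype(0.4, 0.4, 0.0, rng) == pytest.approx(0.4)
        assert offspring_phenotype(0.2, 0.6, 0.0, rng) == pytest.approx(0.4)

    def test_mutants_are_uniform(self, rng):
        draws = np.array([offspring_phenotype(0.3, 0.3, 1.0, rng) for _ in range(10_000)])
        assert stats.kstest(draws, "uniform").pvalue > 0.01

    @given(pm=unit, pf=unit, phi=unit)
    def test_result_in_unit_interval(self, pm, pf, phi):
        rng = np.random.default_rng(99)
        assert 0.0 <= offspring_phenotype(pm, pf, phi, rng) <= 1.0


class TestSimulationParams:
    def test_season_must_exceed_lifetime_matings(self):
        with pytest.raises(ValueError, match="delta"):
            SimulationParams(delta=3, beta=4)

    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError):
            SimulationParams(gamma=1.5)
        with pytest.raises(ValueError):
            SimulationParams(S=0.7)
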