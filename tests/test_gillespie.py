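import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retrofix import gillespie as g

from conftest import make_population


def _parents(L, mom_genome, dad_genome, mom_infected=False):
    """K=4 population: one female (slot 0), one male (slot 1), two empty."""
    return make_population(
        4,
        L,
        [
            {"sex": 1, "genome": mom_genome, "infected": mom_infected},
            {"sex": 0, "genome": dad_genome},
        ],
    )


def _births(pop, params, n, seed=1):
    """Repeat the birth primitive n times from the same parental state,
    yielding (copy_count, infected) of each offspring."""
    g.seed_event_rng(seed)
    out = []
    for _ in range(n):
        slot = g._birth_event(
            0.0, pop.genome, pop.l, pop.sex, pop.inf, pop.alive, pop.tb,
            pop.by_type, pop.pos_type, pop.cnt_type,
            pop.by_sex, pop.pos_sex, pop.cnt_sex,
            pop.empty_lst, pop.pos_empty, pop.cnt_empty,
            pop.S, params.L, params.m, params.alpha, params.beta,
        )
        out.append((int(pop.l[slot]), bool(pop.inf[slot])))
        pop.alive[slot] = 0
        pop.rebuild_lists()
    return out


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"beta": 1.5, "alpha": 1.0},
            {"m": -0.1},
            {"m": 0.5, "alpha": 0.0},
            {"L": 0},
            {"r": -1.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            g.StochasticParams(**kwargs)

    def test_death_rates(self):
        p = g.StochasticParams(x=1.0, y=0.5)
        assert p.vX == pytest.approx(0.2 * math.e)
        assert p.vE == pytest.approx(0.2 * math.exp(0.5))
        assert p.vEX == p.vX
        assert g.StochasticParams(x=0.1, y=0.5).vEX == pytest.approx(
            0.2 * math.exp(0.5)
        )


class TestRates:
    def test_empty_population(self):
        pop = make_population(10, 2, [])
        params = g.StochasticParams(K=10, L=2)
        assert np.all(g.compute_rates(pop, params) == 0.0)

    def test_birth_rate_vanishes_at_capacity(self):
        members = [{"sex": i % 2} for i in range(6)]
        pop = make_population(6, 1, members)
        params = g.StochasticParams(K=6, L=1, x=0.0, m=0.0)
        rates = g.compute_rates(pop, params)
        assert rates[0] == 0.0
        assert rates[1] == pytest.approx(0.2 * 6)

    def test_birth_rate_requires_a_male(self):
        pop = make_population(8, 1, [{"sex": 1}, {"sex": 1}])
        params = g.StochasticParams(K=8, L=1)
        assert g.compute_rates(pop, params)[0] == 0.0

    def test_birth_rate_per_female(self):
        pop = make_population(8, 1, [{"sex": 1}, {"sex": 1}, {"sex": 0}])
        params = g.StochasticParams(K=8, L=1, b0=1.0)
        # 2*b0*NF*(1 - Ntot/K) = 2*1*2*(1 - 3/8)
        assert g.compute_rates(pop, params)[0] == pytest.approx(2.0 * 2 * 0.625)

    def test_transposition_rate_formula(self):
        genome = np.zeros(20, dtype=int)
        genome[3] = 1
        pop = make_population(4, 10, [{"sex": 0, "genome": genome}])
        params = g.StochasticParams(K=4, L=10, r=0.1)
        # r*l*(1 - l/2L) = 0.1 * 1 * (1 - 1/20)
        assert g.compute_rates(pop, params)[7] == pytest.approx(0.095)

    def test_transposition_stops_at_saturation(self):
        pop = make_population(4, 3, [{"sex": 0, "genome": [1] * 6}])
        params = g.StochasticParams(K=4, L=3, r=0.5)
        assert g.compute_rates(pop, params)[7] == pytest.approx(0.0)

    def test_infectious_pool_includes_both_infected_types(self):
        members = [
            {"sex": 0},  # type 0
            {"sex": 1, "infected": True},  # type X
            {"sex": 0, "genome": [1, 0], "infected": True},  # type EX
            {"sex": 1, "genome": [0, 1]},  # type E
        ]
        pop = make_population(10, 1, members)
        params = g.StochasticParams(K=10, L=1, x=1.0, alpha=1.0, beta=0.25)
        rates = g.compute_rates(pop, params)
        force = 1.0 * (1 + 1) / 10  # x*(NX+NEX)/K
        assert rates[5] == pytest.approx(1.0 * force * 1)  # one susceptible 0
        assert rates[6] == pytest.approx(0.25 * force * 1)  # one carrier


class TestBirthEvent:
    def test_homozygous_parents_give_full_copy_number(self):
        L = 3
        pop = _parents(L, [1] * 6, [1] * 6)
        params = g.StochasticParams(K=4, L=L, r=0.0)
        for lc, _ in _births(pop, params, 30):
            assert lc == 2 * L

    def test_heterozygous_cross_carrier_fraction(self):
        # one heterozygous locus in each parent: offspring carries >= 1 copy
        # with probability 3/4
        pop = _parents(1, [1, 0], [1, 0])
        params = g.StochasticParams(K=4, L=1, r=0.0)
        n = 10_000
        carriers = sum(lc > 0 for lc, _ in _births(pop, params, n, seed=11))
        se = math.sqrt(0.75 * 0.25 / n)
        assert abs(carriers / n - 0.75) < 3 * se

    def test_maternal_transmission_frequency(self):
        pop = _parents(1, [0, 0], [0, 0], mom_infected=True)
        params = g.StochasticParams(K=4, L=1, m=0.5, r=0.0, x=1.0)
        n = 10_000
        infected = sum(i for _, i in _births(pop, params, n, seed=7))
        se = math.sqrt(0.25 / n)
        assert abs(infected / n - 0.5) < 3 * se

    def test_carrier_offspring_protected_when_beta_zero(self):
        # infected mother, homozygous-carrier father: every offspring inherits
        # a copy, so with beta=0 none is maternally infected
        pop = _parents(1, [0, 0], [1, 1], mom_infected=True)
        params = g.StochasticParams(K=4, L=1, m=1.0, beta=0.0, r=0.0, x=1.0)
        for lc, infected in _births(pop, params, 500, seed=3):
            assert lc >= 1
            assert not infected

    def test_carrier_offspring_reduced_maternal_rate(self):
        # m * beta / alpha = 0.8 * 0.5 / 1.0 = 0.4 for carrier offspring
        pop = _parents(1, [0, 0], [1, 1], mom_infected=True)
        params = g.StochasticParams(K=4, L=1, m=0.8, beta=0.5, alpha=1.0, r=0.0, x=1.0)
        n = 10_000
        infected = sum(i for _, i in _births(pop, params, n, seed=5))
        se = math.sqrt(0.4 * 0.6 / n)
        assert abs(infected / n - 0.4) < 3 * se


class TestEventSelection:
    def test_two_class_race_frequencies(self):
        # two males: one non-carrier (death rate v0), one carrier with
        # y = ln 3 (death rate 3*v0). No females, so deaths are the only
        # events. The carrier dies first with probability 3/4 (-> loss);
        # otherwise the survivor is a lone carrier (-> fixation).
        members = [{"sex": 0}, {"sex": 0, "genome": [1, 0]}]
        params = g.StochasticParams(K=2, L=1, y=math.log(3.0), r=0.0, x=0.0, m=0.0)
        n = 20_000
        pop = make_population(2, 1, members)
        fix = 0
        for i in range(n):
            out = g.run_replicate(params, population=pop, seed=i)
            fix += out.outcome == "fixation"
        se = math.sqrt(0.25 * 0.75 / n)
        assert abs(fix / n - 0.25) < 3 * se

    def test_fixed_seed_reproducibility(self, steady_x1):
        params = g.StochasticParams(x=1.0, m=0.0, y=0.1, r=0.05, K=300)
        p0, pX = steady_x1
        a = g.run_replicate(params, xrv_present=True, seed=42, p0=p0, pX=pX,
                            sample_dt=5.0)
        b = g.run_replicate(params, xrv_present=True, seed=42, p0=p0, pX=pX,
                            sample_dt=5.0)
        assert a.outcome == b.outcome
        assert a.t_end == b.t_end
        assert np.array_equal(a.trajectory, b.trajectory)


class TestTransposition:
    def test_single_carrier_saturates(self):
        pop = make_population(1, 1, [{"sex": 0, "genome": [1, 0]}])
        g.seed_event_rng(0)
        g._transposition_event(pop.genome, pop.l, pop.by_type, pop.cnt_type,
                               pop.S, 2.0)
        assert pop.l[0] == 2
        assert pop.genome[0].tolist() == [1, 1]
        assert pop.S[0] == 2 and pop.S[1] == 4

    def test_weighted_selection_skips_saturated(self):
        # carrier A saturated (weight 0), carrier B with l=1 (weight 0.5):
        # B must always be chosen
        members = [
            {"sex": 0, "genome": [1, 1]},
            {"sex": 1, "genome": [1, 0]},
        ]
        g.seed_event_rng(9)
        for _ in range(50):
            pop = make_population(2, 1, members)
            g._transposition_event(pop.genome, pop.l, pop.by_type,
                                   pop.cnt_type, pop.S, 2.0)
            assert pop.l[1] == 2


class TestInitPopulation:
    def test_expected_census_and_single_seed(self):
        params = g.StochasticParams(K=1000, L=10)
        rng = np.random.default_rng(0)
        pop, retries = g.init_population(params, False, rng, p0=0.8)
        n = pop.counts()
        se = math.sqrt(1000 * 0.8 * 0.2)
        assert abs(n["Ntot"] - 800) < 4 * se
        assert n["C"] == 1  # exactly one seeded allele
        assert n["NE"] == 1 and n["NEX"] == 0 and n["NX"] == 0
        assert retries == 0

    def test_xrv_seed_goes_into_infected_individual(self, steady_x1):
        params = g.StochasticParams(K=1000, L=10, x=1.0, m=0.0)
        p0, pX = steady_x1
        rng = np.random.default_rng(1)
        pop, _ = g.init_population(params, True, rng, p0=p0, pX=pX)
        n = pop.counts()
        assert n["NEX"] == 1 and n["NE"] == 0
        assert n["C"] == 1

    def test_impossible_seed_raises(self):
        params = g.StochasticParams(K=50, L=1)
        rng = np.random.default_rng(2)
        with pytest.raises(RuntimeError):
            g.init_population(params, True, rng, p0=0.8, pX=0.0, max_retries=20)


class TestReplicates:
    def test_tally_audit_after_run(self, steady_x1):
        p0, pX = steady_x1
        for seed in range(5):
            params = g.StochasticParams(K=200, L=3, x=1.0, m=0.0, y=0.1, r=0.1)
            out = g.run_replicate(params, xrv_present=True, seed=seed,
                                  p0=p0, pX=pX)
            out.final_population.audit()
            assert out.outcome in g.OUTCOME_NAMES

    def test_full_resistance_never_creates_new_infected_carriers(self, steady_x1):
        # beta=0: the seed EX individual is the only one ever; NEX can only
        # decrease along the whole trajectory
        p0, pX = steady_x1
        params = g.StochasticParams(x=1.0, m=0.0, y=0.0, r=0.1, beta=0.0)
        for seed in (0, 1, 2):
            out = g.run_replicate(params, xrv_present=True, seed=seed,
                                  p0=p0, pX=pX, sample_dt=1.0)
            nex = out.trajectory[:, 4]
            assert nex[0] <= 1
            assert np.all(np.diff(nex) <= 0)

    def test_clearance_pathway_occurs(self, steady_x1):
        # ERV fitter than the XRV but costlier than uninfected hosts: the
        # insertion can purge the XRV and then be purged itself
        p0, pX = steady_x1
        params = g.StochasticParams(x=1.0, m=0.0, y=0.1, r=0.01, beta=0.0)
        codes = g.run_replicates(params, True, 300, 2024, p0, pX)
        assert np.any(codes == g.CLEARANCE)
        # clearance implies the XRV disappeared strictly before the ERV
        for seed in range(300):
            out = g.run_replicate(params, xrv_present=True, seed=2024 + seed,
                                  p0=p0, pX=pX)
            if out.outcome == "clearance":
                assert out.t_xrv_eliminated is not None
                assert out.t_xrv_eliminated < out.t_end
                break

    def test_lone_survivor_classification(self):
        # a lone carrier is by definition a fixed state (no one lacks a copy)
        pop = make_population(3, 1, [{"sex": 1, "genome": [1, 0]}])
        params = g.StochasticParams(K=3, L=1, r=0.0, x=0.0, m=0.0)
        out = g.run_replicate(params, population=pop, seed=0)
        assert out.outcome == "fixation"
        assert out.t_end == 0.0


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 10_000), k=st.integers(2, 30), L=st.integers(1, 4))
def test_random_population_rate_invariants(seed, k, L):
    """All event-class rates are non-negative, and tallies match a recount."""
    rng = np.random.default_rng(seed)
    members = []
    for _ in range(rng.integers(0, k + 1)):
        members.append(
            {
                "sex": int(rng.integers(2)),
                "infected": bool(rng.integers(2)),
                "genome": rng.integers(0, 2, 2 * L),
            }
        )
    pop = make_population(k, L, members)
    pop.audit()
    params = g.StochasticParams(K=k, L=L, x=0.7, m=0.3, y=0.2, r=0.4, beta=0.5)
    rates = g.compute_rates(pop, params)
    assert np.all(rates >= 0.0)
    n = pop.counts()
    if n["Ntot"] == k or n["NM"] == 0:
        assert rates[0] == 0.0
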