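import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from t2dmscreen.errors import ContractError
from t2dmscreen.life_table import adjusted_mortality
from t2dmscreen.microsim import (HealthState, accrue, annual_transition,
                                 discount_factor, run_cohort_expectation,
                                 run_microsim, screening_event, simulate_individual)
from t2dmscreen.parameters import TestCharacteristics
from t2dmscreen.reference import reference_preset, stratum

from conftest import flat_life_table, make_config, random_toy_config

H, FP, U, T, C, D = HealthState


class TestDiscountFactor:
    def test_cycle_zero_is_one(self):
        assert discount_factor(0, 0.02) == 1.0

    def test_one_cycle(self):
        assert discount_factor(1, 0.02) == pytest.approx(1 / 1.02, abs=1e-12)

    def test_geometric_sum_closed_form(self):
        d = 0.02
        total = sum(discount_factor(t, d) for t in range(55))
        r = 1 / (1 + d)
        assert total == pytest.approx((1 - r ** 55) / (1 - r), abs=1e-9)

    @given(st.integers(0, 40), st.integers(0, 40))
    def test_multiplicative(self, t1, t2):
        d = 0.03
        assert discount_factor(t1 + t2, d) == pytest.approx(
            discount_factor(t1, d) * discount_factor(t2, d), rel=1e-12)


class TestAccrue:
    def test_dead_accrues_nothing(self):
        cfg = make_config()
        assert accrue(D, cfg) == (0.0, 0.0)

    def test_reference_complication_state(self):
        cfg = reference_preset(stratum(60, "obese"), annual_incidence=0.02)
        assert accrue(C, cfg) == (8000.0, 0.638)
        assert accrue(FP, cfg) == (1400.0, 1.0)
        assert accrue(U, cfg) == (0.0, 0.785)
        assert accrue(T, cfg) == (3500.0, 0.785)


class TestScreeningEvent:
    def test_perfect_sensitivity_detects(self):
        tc = TestCharacteristics("x", 1, 1.0, 1.0)
        rng = np.random.default_rng(0)
        assert screening_event(U, tc, rng) is T

    def test_perfect_specificity_never_flags(self):
        tc = TestCharacteristics("x", 1, 0.5, 1.0)
        rng = np.random.default_rng(0)
        assert all(screening_event(H, tc, rng) is H for _ in range(100))

    def test_called_on_treated_is_a_contract_violation(self):
        tc = TestCharacteristics("x", 1, 0.5, 0.9)
        with pytest.raises(ContractError):
            screening_event(T, tc, np.random.default_rng(0))

    def test_false_positive_rate_matches_binomial(self):
        """At specificity 0.991, healthy screens flag ~0.9% false positives."""
        tc = TestCharacteristics("x", 1, 0.5, 0.991)
        rng = np.random.default_rng(123)
        n = 200_000
        flags = sum(screening_event(H, tc, rng) is FP for _ in range(n))
        p = 0.009
        se = math.sqrt(p * (1 - p) / n)
        assert abs(flags / n - p) <= 3 * se

    def test_false_positive_reverts_on_true_negative(self):
        tc = TestCharacteristics("x", 1, 0.5, 1.0)
        rng = np.random.default_rng(0)
        assert screening_event(FP, tc, rng) is H


class TestAnnualTransition:
    def test_null_dynamics_leaves_state(self, toy_lt):
        cfg = make_config(incidence=0.0, comp_rate=0.0)
        lt = flat_life_table(0.0)
        rng = np.random.default_rng(0)
        for s in (H, FP, U, T, C):
            assert annual_transition(s, cfg.risks, lt, 70, rng) is s

    def test_dead_is_a_contract_violation(self, toy_lt):
        cfg = make_config()
        with pytest.raises(ContractError):
            annual_transition(D, cfg.risks, toy_lt, 70, np.random.default_rng(0))

    def test_complication_rate_matches_binomial(self):
        cfg = make_config(incidence=0.0, comp_rate=0.014)
        lt = flat_life_table(0.0)
        rng = np.random.default_rng(5)
        n = 200_000
        hits = sum(annual_transition(U, cfg.risks, lt, 70, rng) is C for _ in range(n))
        se = math.sqrt(0.014 * 0.986 / n)
        assert abs(hits / n - 0.014) <= 3 * se

    def test_complication_mortality_matches_hazard_scale_rr(self):
        cfg = make_config(comp_rate=0.0)
        lt = flat_life_table(0.01)
        rng = np.random.default_rng(9)
        n = 200_000
        deaths = sum(annual_transition(C, cfg.risks, lt, 70, rng) is D for _ in range(n))
        p = 1 - 0.99 ** 5.22  # ~0.05112
        se = math.sqrt(p * (1 - p) / n)
        assert abs(deaths / n - p) <= 3 * se


def enumerate_expectation(cfg, strategy, lt):
    """Independent oracle: exhaustive enumeration of every outcome path.

    Walks the event tree (screen outcome, incidence, complication, death)
    cycle by cycle, multiplying branch probabilities; exact for small
    horizons.  Kept deliberately recursive and scalar, sharing no code with
    the engine.
    """
    s, r, costs, utils = cfg.settings, cfg.risks, cfg.costs, cfg.utilities
    entry = s.entry_age
    state_cost = {H: 0.0, FP: costs.fp_annual, U: 0.0, T: costs.tx_no_comp_annual,
                  C: costs.tx_comp_annual, D: 0.0}
    state_util = {H: utils.healthy, FP: utils.healthy, U: utils.t2dm_no_comp,
                  T: utils.t2dm_no_comp, C: utils.t2dm_comp, D: 0.0}
    cr_treated = adjusted_mortality(r.annual_comp_rate, r.rr_comp_treated)
    mort_rr = {H: 1.0, FP: 1.0, U: r.rr_mort_untreated, T: r.rr_mort_treated,
               C: r.rr_mort_comp}
    total = {"cost": 0.0, "qaly": 0.0}

    def screen_branches(state):
        sens, spec = strategy.sensitivity, strategy.specificity
        if state is U:
            return [(sens, T), (1 - sens, U)]
        if state is H:
            return [(1 - spec, FP), (spec, H)]
        if state is FP:
            return [(spec, H), (1 - spec, FP)]
        return [(1.0, state)]

    def incidence_branches(state):
        if state in (H, FP):
            return [(r.annual_incidence, U), (1 - r.annual_incidence, state)]
        return [(1.0, state)]

    def comp_branches(state):
        if state is U:
            return [(r.annual_comp_rate, C), (1 - r.annual_comp_rate, U)]
        if state is T:
            return [(cr_treated, C), (1 - cr_treated, T)]
        return [(1.0, state)]

    def walk(t, state, prob):
        if prob == 0.0 or state is D or entry + t >= s.max_age:
            return
        df = (1 + s.discount_rate) ** (-t)
        screened = t % strategy.interval_years == 0 and state in (H, FP, U)
        if screened:
            total["cost"] += prob * costs.screening_cost * df
        for p1, s1 in (screen_branches(state) if screened else [(1.0, state)]):
            for p2, s2 in incidence_branches(s1):
                for p3, s3 in comp_branches(s2):
                    qx = float(lt.qx_at(entry + t))
                    p_die = 1 - (1 - qx) ** mort_rr[s3]
                    for p4, s4 in [(p_die, D), (1 - p_die, s3)]:
                        p = prob * p1 * p2 * p3 * p4
                        if p == 0.0:
                            continue
                        total["cost"] += p * state_cost[s4] * df
                        total["qaly"] += p * state_util[s4] * df
                        walk(t + 1, s4, p)

    walk(0, H, 1.0)
    return total["cost"], total["qaly"]


class TestCohortExpectation:
    def test_zero_risk_undiscounted_qaly_is_exact_horizon(self):
        cfg = make_config(incidence=0.0, discount=0.0, entry_age=60, max_age=85,
                          screening_cost=50.0,
                          strategies=(TestCharacteristics("annual", 1, 0.0, 1.0),
                                      TestCharacteristics("3-year", 3, 0.0, 1.0)))
        lt = flat_life_table(0.0)
        res = run_cohort_expectation(cfg, cfg.strategies[1], lt)
        assert res.mean_qaly == pytest.approx(25.0, abs=1e-9)
        assert res.mean_cost == pytest.approx(50.0 * math.ceil(25 / 3), abs=1e-9)

    def test_matches_exhaustive_path_enumeration(self):
        """Exact agreement with an independent full path-tree enumeration on a
        three-cycle model."""
        for interval in (1, 2):
            cfg = make_config(incidence=0.3, comp_rate=0.2, rr_comp_treated=0.5,
                              rr_mort_comp=3.0, rr_mort_untreated=2.0,
                              entry_age=70, max_age=73,
                              strategies=(TestCharacteristics("a", interval, 0.7, 0.9),
                                          TestCharacteristics("b", 5, 0.5, 0.9)))
            lt = flat_life_table(0.05)
            res = run_cohort_expectation(cfg, cfg.strategies[0], lt)
            cost, qaly = enumerate_expectation(cfg, cfg.strategies[0], lt)
            assert res.mean_cost == pytest.approx(cost, abs=1e-12)
            assert res.mean_qaly == pytest.approx(qaly, abs=1e-12)

    def test_perfect_test_qaly_monotone_in_interval(self):
        lt = flat_life_table(0.01)
        qalys = []
        for k in (1, 2, 4, 8):
            cfg = make_config(screening_cost=0.0, rr_mort_treated=1.0,
                              rr_mort_untreated=2.61,
                              strategies=(TestCharacteristics("k", k, 1.0, 1.0),
                                          TestCharacteristics("other", 50, 1.0, 1.0)))
            qalys.append(run_cohort_expectation(cfg, cfg.strategies[0], lt).mean_qaly)
        assert all(a >= b - 1e-12 for a, b in zip(qalys, qalys[1:]))

    def test_zero_sensitivity_strategies_differ_only_by_screening_schedule(self):
        lt = flat_life_table(0.01)
        outcomes = {}
        for k in (1, 3):
            strategies = (TestCharacteristics("a", k, 0.0, 1.0),
                          TestCharacteristics("b", 7, 0.0, 1.0))
            with_fee = make_config(strategies=strategies, screening_cost=100.0)
            free = make_config(strategies=strategies, screening_cost=0.0)
            outcomes[k] = (run_cohort_expectation(with_fee, strategies[0], lt),
                           run_cohort_expectation(free, strategies[0], lt))
        (fee1, free1), (fee3, free3) = outcomes[1], outcomes[3]
        assert fee1.mean_qaly == pytest.approx(fee3.mean_qaly, abs=1e-9)
        assert free1.mean_cost == pytest.approx(free3.mean_cost, abs=1e-9)
        assert fee1.mean_cost - free1.mean_cost > fee3.mean_cost - free3.mean_cost


class TestRunMicrosim:
    def test_zero_risk_closed_form(self):
        cfg = make_config(incidence=0.0, discount=0.0, entry_age=62, max_age=80,
                          screening_cost=100.0,
                          strategies=(TestCharacteristics("annual", 1, 0.0, 1.0),
                                      TestCharacteristics("4-year", 4, 0.0, 1.0)))
        lt = flat_life_table(0.0)
        res = run_microsim(cfg, cfg.strategies[1], lt, n=200, seed=1)
        assert res.mean_qaly == pytest.approx(18.0, abs=1e-12)
        assert res.mean_cost == pytest.approx(100.0 * math.ceil(18 / 4), abs=1e-12)
        assert res.se_qaly == 0.0

    def test_immediate_death_accrues_only_first_screen(self):
        cfg = make_config(entry_age=70, age_low=70, age_high=74, max_age=85)
        lt = flat_life_table(0.0)
        q = lt.qx.copy()
        q[70:] = 1.0
        lt = dataclasses.replace(lt, qx=q)
        res = run_microsim(cfg, cfg.strategies[0], lt, n=100, seed=2)
        assert res.mean_qaly == 0.0
        assert res.mean_cost == pytest.approx(cfg.costs.screening_cost)

    def test_identical_seed_bit_identical(self, toy_lt):
        cfg = make_config(entry_age=None)
        a = run_microsim(cfg, cfg.strategies[1], toy_lt, n=3000, seed=42)
        b = run_microsim(cfg, cfg.strategies[1], toy_lt, n=3000, seed=42)
        assert a == b

    def test_different_seeds_agree_within_six_combined_se(self, toy_lt):
        cfg = make_config(entry_age=None)
        a = run_microsim(cfg, cfg.strategies[1], toy_lt, n=20_000, seed=1)
        b = run_microsim(cfg, cfg.strategies[1], toy_lt, n=20_000, seed=2)
        se_q = math.hypot(a.se_qaly, b.se_qaly)
        se_c = math.hypot(a.se_cost, b.se_cost)
        assert abs(a.mean_qaly - b.mean_qaly) <= 6 * se_q
        assert abs(a.mean_cost - b.mean_cost) <= 6 * se_c

    def test_strategy_not_in_config_is_a_contract_violation(self, toy_lt):
        cfg = make_config()
        with pytest.raises(ContractError):
            run_microsim(cfg, TestCharacteristics("alien", 2, 0.5, 0.9), toy_lt, n=10)

    @pytest.mark.parametrize("case", range(5))
    def test_agrees_with_cohort_oracle_on_random_toy_configs(self, case, toy_lt):
        rng = np.random.default_rng(100 + case)
        cfg = random_toy_config(rng)
        for tc in cfg.strategies:
            micro = run_microsim(cfg, tc, toy_lt, n=20_000, seed=case)
            cohort = run_cohort_expectation(cfg, tc, toy_lt)
            assert abs(micro.mean_qaly - cohort.mean_qaly) <= 3 * micro.se_qaly
            assert abs(micro.mean_cost - cohort.mean_cost) <= 3 * micro.se_cost


class TestSimulateIndividual:
    def test_perfect_test_never_false_positive_and_detects_at_screen(self, toy_lt):
        cfg = make_config(strategies=(TestCharacteristics("annual", 1, 1.0, 1.0),
                                      TestCharacteristics("3-year", 3, 1.0, 1.0)))
        rng = np.random.default_rng(0)
        for _ in range(300):
            trace = []
            simulate_individual(cfg, cfg.strategies[0], toy_lt, rng, 65, trace=trace)
            states = [row["state"] for row in trace]
            assert "FALSE_POSITIVE" not in states
            # annual perfect screening: an undetected case never survives to the
            # next cycle still undetected — the next screen always catches it
            for a, b in zip(states, states[1:]):
                assert not (a == "UNDETECTED_T2DM" and b == "UNDETECTED_T2DM")

    def test_zero_sensitivity_never_treated_before_complication(self, toy_lt):
        cfg = make_config(strategies=(TestCharacteristics("annual", 1, 0.0, 1.0),
                                      TestCharacteristics("3-year", 3, 0.0, 1.0)))
        rng = np.random.default_rng(1)
        for _ in range(300):
            trace = []
            simulate_individual(cfg, cfg.strategies[0], toy_lt, rng, 65, trace=trace)
            assert all(row["state"] != "TREATED_T2DM" for row in trace)

    def test_mean_agrees_with_cohort(self, toy_lt):
        cfg = make_config()
        rng = np.random.default_rng(7)
        n = 4000
        res = [simulate_individual(cfg, cfg.strategies[1], toy_lt, rng, 60)
               for _ in range(n)]
        qalys = np.array([r["discounted_qaly"] for r in res])
        cfg_fixed = make_config(entry_age=60)
        cohort = run_cohort_expectation(cfg_fixed, cfg_fixed.strategies[1], toy_lt)
        se = qalys.std(ddof=1) / np.sqrt(n)
        assert abs(qalys.mean() - cohort.mean_qaly) <= 3 * se
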