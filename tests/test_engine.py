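"""Cow-value engine against closed forms and the Monte-Carlo oracle."""

import numpy as np
import pytest
import scipy.sparse as sp

from cowvalue import CowState, ScenarioSpec, monte_carlo_oracle
from cowvalue.engine import (TruncationWarning, apply_scenario,
                             expected_event_count, expected_remaining_months,
                             expected_total_cash, occupancy_trajectory,
                             simulate_paths)
from cowvalue.states import build_state_space
from cowvalue.transitions import TransitionModel
from cowvalue.records import REASONS


def geometric_Q(q):
    return np.array([[1.0 - q]])


class TestClosedForms:
    @pytest.mark.parametrize("q,expected", [(0.05, 20.0), (0.5, 2.0), (0.1, 10.0)])
    def test_geometric_lifetime_is_one_over_q(self, q, expected):
        assert expected_remaining_months(geometric_Q(q), 0) == pytest.approx(
            expected, abs=1e-9)

    def test_geometric_survival_curve(self):
        occ, absorbed = occupancy_trajectory(geometric_Q(0.05), 0, horizon=600)
        t = np.arange(len(occ))
        np.testing.assert_allclose(occ[:, 0], 0.95 ** t, atol=1e-12)
        np.testing.assert_allclose(absorbed, 0.05 * 0.95 ** t, atol=1e-12)

    def test_constant_net_average_is_that_net(self):
        # with a constant per-month net and no terminal income, the average
        # MCM equals the constant for any chain
        q = 0.2
        total = expected_total_cash(geometric_Q(q), [100.0], 0)
        months = expected_remaining_months(geometric_Q(q), 0)
        assert total / months == pytest.approx(100.0, abs=1e-9)

    def test_geometric_average_with_terminal_income(self):
        # net 100/month, terminal carcass 1000, q = 0.1:
        # average = (100 * 10 + 1000) / 10
        q = 0.1
        cash = [100.0 + q * 1000.0]
        total = expected_total_cash(geometric_Q(q), cash, 0)
        months = expected_remaining_months(geometric_Q(q), 0)
        assert total / months == pytest.approx((100 * 10 + 1000) / 10, abs=1e-9)

    def test_certain_cull_before_calving_gives_zero_parities(self, space):
        K = space.n_transient
        split = np.zeros((K, len(REASONS)))
        model = TransitionModel(space, np.ones(K), split, np.zeros(K))
        calve_prob = (1.0 - model.p_cull) * model.is_calving
        assert expected_event_count(model.Q(), calve_prob, 0) == 0.0

    def test_exactly_one_calving_then_cull(self):
        # parity 1 always conceives at month 2 and survives; every parity-2
        # state culls immediately -> exactly one future calving
        space = build_state_space(2, 12)
        K = space.n_transient
        p_cull = np.zeros(K)
        p_conceive = np.zeros(K)
        for i, s in enumerate(space.states):
            if s.parity == 2:
                p_cull[i] = 1.0
            elif space.conception_eligible(s):
                p_conceive[i] = 1.0
        split = np.zeros((K, len(REASONS)))
        model = TransitionModel(space, p_cull, split, p_conceive)
        calve_prob = (1.0 - model.p_cull) * model.is_calving
        parities = expected_event_count(model.Q(), calve_prob,
                                        space.index(CowState(1, 1, 0)))
        assert parities == pytest.approx(1.0, abs=1e-9)


class TestConservation:
    def test_total_probability_conserved_every_month(self, default_engine):
        occ, absorbed = default_engine.occupancy(CowState(1, 1, 0))
        alive = occ.sum(axis=1)
        cum_absorbed = np.cumsum(absorbed.sum(axis=1))
        total = alive + np.concatenate([[0.0], cum_absorbed[:-1]])
        np.testing.assert_allclose(total, 1.0, atol=1e-12)

    def test_trajectory_and_solve_agree_on_expected_months(self, default_engine):
        for state in (CowState(1, 1, 0), CowState(3, 7, 2), CowState(5, 12, 9)):
            # tol=0: iterate the full horizon; forced-cull boundaries make
            # absorption exact within p_max * m_max months
            occ, _ = default_engine.occupancy(state, tol=0.0)
            assert occ.sum() == pytest.approx(
                default_engine.expected_remaining_months(state), abs=1e-9)

    def test_truncation_warning_on_short_horizon(self):
        with pytest.warns(TruncationWarning):
            occupancy_trajectory(geometric_Q(0.01), 0, horizon=10)


class TestCowValue:
    def test_identical_heifer_with_free_replacement_is_worth_zero(
            self, truth_model, truth_curves, econ, default_truth):
        from cowvalue.engine import CowValueEngine
        free = econ.model_copy(update={"heifer_cost": 0.0})
        engine = CowValueEngine(truth_model, free, truth_curves,
                                default_truth.fat_mean,
                                default_truth.protein_mean)
        result = engine.cow_value(CowState(1, 1, 0))
        assert result.cow_value == pytest.approx(0.0, abs=1e-9)

    def test_heifer_cost_makes_incumbent_valuable(self, default_engine):
        result = default_engine.cow_value(CowState(1, 1, 0))
        assert result.cow_value > 0
        assert result.cow_value == (result.avg_mcm_cow
                                    - result.avg_mcm_replacement)
        assert result.expected_remaining_months > 0

    def test_pregnancy_raises_cow_value(self, default_engine):
        open_ = default_engine.cow_value(CowState(1, 5, 0)).cow_value
        pregnant = default_engine.cow_value(CowState(1, 5, 1)).cow_value
        assert pregnant > open_

    def test_absorbed_start_rejected(self, default_engine):
        with pytest.raises(KeyError):
            default_engine.cow_value(CowState(99, 1, 0))


class TestScenarios:
    def test_neutral_scenario_is_identity(self, default_engine):
        state = CowState(1, 6, 0)
        base = default_engine.cow_value(state)
        neutral = apply_scenario(default_engine, state, ScenarioSpec())
        assert neutral.cow_value == pytest.approx(base.cow_value, abs=1e-12)

    def test_lower_yield_reduces_value_everywhere(self, default_engine):
        spec = ScenarioSpec(yield_multiplier=0.9)
        states = ([CowState(1, m, 0) for m in range(2, 11)]
                  + [CowState(1, m, 1) for m in range(3, 10)])
        for s in states:
            assert (apply_scenario(default_engine, s, spec).cow_value
                    < default_engine.cow_value(s).cow_value)

    def test_health_shock_reduces_value(self, default_engine):
        spec = ScenarioSpec(one_time_cost=800.0)
        s = CowState(1, 5, 0)
        assert (apply_scenario(default_engine, s, spec).cow_value
                < default_engine.cow_value(s).cow_value)

    def test_shock_additivity_exact(self, default_engine):
        # a one-time cost C lowers the expected total MCM by exactly
        # C x P(survive to the charged month)
        s = CowState(2, 4, 0)
        i = default_engine.space.index(s)
        n = default_engine.expected_remaining_months(s)
        base_total = default_engine.average_mcm(s) * n
        shocked_total = default_engine.average_mcm(s, one_time_cost=800.0) * n
        survive = 1.0 - default_engine.model.p_cull[i]
        assert base_total - shocked_total == pytest.approx(800.0 * survive,
                                                           abs=1e-9)

    def test_pregnancy_override_reseeds_state(self, default_engine):
        s = CowState(1, 5, 0)
        overridden = default_engine.cow_value(
            s, scenario=ScenarioSpec(pregnancy_override=1))
        direct = default_engine.cow_value(CowState(1, 5, 1))
        assert overridden.cow_value == pytest.approx(direct.cow_value, abs=1e-12)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec(yield_multiplier=0.0)
        with pytest.raises(ValueError):
            ScenarioSpec(one_time_cost=-5.0)


class TestMonteCarlo:
    def test_geometric_chain_mean_lifetime(self):
        rng = np.random.default_rng(3)
        q = 0.1
        months, calvings, cash = simulate_paths(
            p_cull=np.array([q]), p_conceive=np.array([0.0]),
            next_continue=np.array([0]), next_conceive=np.array([-1]),
            is_calving=np.array([False]), base_cash=np.array([100.0]),
            cull_income_carcass=1000.0, p_sold_alive=np.array([0.0]),
            live_sale_value=0.0, start=0, n_paths=40_000, rng=rng,
            horizon=2000)
        se = months.std(ddof=1) / np.sqrt(len(months))
        assert abs(months.mean() - 1 / q) <= 3 * se
        # every path earns 100/month plus the terminal 1000
        np.testing.assert_allclose(cash, 100.0 * months + 1000.0)

    def test_same_seed_reproduces_output(self, default_engine):
        a = monte_carlo_oracle(default_engine, CowState(1, 3, 0),
                               n_paths=5000, seed=9)
        b = monte_carlo_oracle(default_engine, CowState(1, 3, 0),
                               n_paths=5000, seed=9)
        assert a == b

    def test_oracle_matches_engine_on_default_chain(self, default_engine):
        state = CowState(2, 6, 0)
        mc = monte_carlo_oracle(default_engine, state, n_paths=60_000, seed=17)
        assert abs(mc.mean_months
                   - default_engine.expected_remaining_months(state)) \
            <= 3 * mc.se_months
        assert abs(mc.mean_parities
                   - default_engine.expected_remaining_parities(state)) \
            <= 3 * mc.se_parities
        assert abs(mc.avg_mcm - default_engine.average_mcm(state)) \
            <= 3 * mc.se_avg_mcm
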