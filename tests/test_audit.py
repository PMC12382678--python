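"""Decision classification, final-state reconstruction, and aggregation."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cowvalue import CowState, classify_decision, reason_by_parity, study_summary
from cowvalue.audit import QUADRANTS, audit_farm, final_state
from cowvalue.engine import CowValueResult
from cowvalue.records import REASONS, CowRecord, CullingEvent
from cowvalue.records import TestDay as MilkTestDay
from cowvalue import reference
from cowvalue.states import build_state_space


class TestClassify:
    @pytest.mark.parametrize("value,culled,expected", [
        (50.0, True, "replaced_too_soon"),
        (-30.0, True, "correctly_culled"),
        (0.0, False, "retained_ok"),
        (0.0, True, "replaced_too_soon"),   # zero is retain-optimal
        (75.0, False, "retained_ok"),
        (-5.0, False, "retained_too_long"),
    ])
    def test_quadrant_mapping(self, value, culled, expected):
        assert classify_decision(value, culled) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_decision(float("nan"), True)
        with pytest.raises(ValueError):
            classify_decision(float("inf"), False)

    @settings(deadline=None, max_examples=100)
    @given(value=st.floats(allow_nan=False, allow_infinity=False,
                           width=32),
           culled=st.booleans())
    def test_quadrants_exhaustive_and_exclusive(self, value, culled):
        q = classify_decision(value, culled)
        assert q in QUADRANTS
        # culled status constrains the reachable quadrants
        if culled:
            assert q in ("replaced_too_soon", "correctly_culled")
        else:
            assert q in ("retained_ok", "retained_too_long")


class TestFinalState:
    def test_state_reconstruction_with_pregnancy(self):
        space = build_state_space(12, 24)
        cow = CowRecord(
            cow_id="B1",
            calvings=[pd.Period("2018-01"), pd.Period("2019-01")],
            inseminations=[pd.Period("2019-03")],
            testdays=[MilkTestDay(pd.Period("2019-06"), 500.0, 4.0, 3.3)],
            culling=None)
        state, last_obs = final_state(cow, pd.Period("2019-06"), space)
        assert last_obs == pd.Period("2019-06")
        assert state == CowState(2, 6, 3)

    def test_insemination_in_last_month_not_yet_pregnant(self):
        space = build_state_space(12, 24)
        cow = CowRecord(cow_id="B2", calvings=[pd.Period("2019-01")],
                        inseminations=[pd.Period("2019-05")])
        state, _ = final_state(cow, pd.Period("2019-12"), space)
        # the last event is the insemination itself: no non-return window
        assert state == CowState(1, 5, 0)

    def test_return_to_service_resets_pregnancy(self):
        space = build_state_space(12, 24)
        cow = CowRecord(cow_id="B3", calvings=[pd.Period("2019-01")],
                        inseminations=[pd.Period("2019-03"),
                                       pd.Period("2019-06")],
                        culling=CullingEvent(pd.Period("2019-07"),
                                             "fertility"))
        state, _ = final_state(cow, pd.Period("2019-12"), space)
        assert state == CowState(1, 7, 1)  # conceived at the second service

    def test_stale_insemination_treated_as_open(self):
        space = build_state_space(12, 24)
        cow = CowRecord(cow_id="B4", calvings=[pd.Period("2018-01")],
                        inseminations=[pd.Period("2018-03")],
                        testdays=[MilkTestDay(pd.Period("2019-05"), 300.0, 4.0,
                                          3.3)])
        # 14 months after the service with no calving: cannot be pregnant
        state, _ = final_state(cow, pd.Period("2019-05"), space)
        assert state == CowState(1, 17, 0)

    def test_heifer_without_calving_is_excluded(self):
        space = build_state_space(12, 24)
        cow = CowRecord(cow_id="B5", inseminations=[pd.Period("2019-05")])
        state, last = final_state(cow, pd.Period("2019-12"), space)
        assert state is None and last is None


class _StubEngine:
    """Duck-typed engine returning preset cow values (for ledger tests)."""

    def __init__(self, values, space):
        self.values = values
        self.space = space
        self.herd_curves = None

    def cow_value(self, state, cow_effect=1.0, scenario=None):
        v = self.values.pop(0)
        return CowValueResult(avg_mcm_cow=v, avg_mcm_replacement=0.0,
                              expected_remaining_months=10.0,
                              expected_remaining_parities=1.0)


class TestFarmLedger:
    def _herd(self, toy_herdbook):
        return toy_herdbook

    def test_single_premature_cull_books_its_value_as_loss(self, toy_herdbook):
        space = build_state_space(12, 24)
        # cows sorted as in the herdbook: A1 (culled), A2 (culled), A3 (alive)
        stub = _StubEngine([75.0, -20.0, 5.0], space)
        audit, records = audit_farm(toy_herdbook, stub, effects={})
        assert audit.replaced_loss == pytest.approx(-75.0)
        assert audit.not_replaced_loss == 0.0
        by_cow = {r.cow_id: r.quadrant for r in records}
        assert by_cow == {"A1": "replaced_too_soon",
                          "A2": "correctly_culled",
                          "A3": "retained_ok"}

    def test_all_optimal_herd_books_no_loss(self, toy_herdbook):
        space = build_state_space(12, 24)
        stub = _StubEngine([-10.0, -20.0, 5.0], space)
        audit, _ = audit_farm(toy_herdbook, stub, effects={})
        assert audit.replaced_loss == 0.0
        assert audit.not_replaced_loss == 0.0

    def test_ledger_conserves_from_cow_to_farm_to_study(self, study_farms,
                                                        default_engine):
        _, farms = study_farms
        audits, all_records = [], []
        for hb in farms:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                audit, records = audit_farm(hb, default_engine)
            audits.append(audit)
            all_records.extend(records)
            replaced = -sum(r.cow_value for r in records
                            if r.quadrant == "replaced_too_soon")
            retained = sum(r.cow_value for r in records
                           if r.quadrant == "retained_too_long")
            assert audit.replaced_loss == pytest.approx(replaced, abs=1e-9)
            assert audit.not_replaced_loss == pytest.approx(retained, abs=1e-9)
            assert audit.replaced_loss <= 0 and audit.not_replaced_loss <= 0
        summary = study_summary(audits)
        assert summary["replaced_loss_total"] == pytest.approx(
            sum(a.replaced_loss for a in audits), abs=1e-9)
        assert summary["n_cows_total"] == sum(a.n_cows for a in audits)


class TestReasonByParity:
    def test_reference_grid_totals_and_shares(self):
        events = reference.culling_events_from_grid()
        grid = reason_by_parity(events, labels=False)
        assert grid.loc["Total replaced", "Total"] == 553
        assert grid.loc["fertility", "Total"] == 146
        assert grid.loc["fertility", "Share"] == 26.4
        assert grid.loc["udder_health", "Share"] == 22.6
        # row and column totals both reproduce the grand total
        reasons = list(REASONS)
        assert grid.loc[reasons, "Total"].sum() == 553
        assert grid.loc["Total replaced", range(1, 13)].sum() == 553

    def test_empty_input_gives_zero_grid(self):
        grid = reason_by_parity([], labels=False)
        assert grid.loc["Total replaced", "Total"] == 0

    def test_unknown_reason_rejected(self):
        with pytest.raises(ValueError):
            reason_by_parity([("alien_abduction", 1)])

    @settings(deadline=None, max_examples=25)
    @given(events=st.lists(st.tuples(st.sampled_from(REASONS),
                                     st.integers(1, 12)), max_size=60))
    def test_marginals_always_sum_to_grand_total(self, events):
        grid = reason_by_parity(events, labels=False)
        n = len(events)
        assert grid.loc["Total replaced", "Total"] == n
        assert grid.loc[list(REASONS), "Total"].sum() == n
        assert grid.loc["Total replaced", range(1, 13)].sum() == n


class TestStudySummary:
    def test_reference_farm_table_sums(self):
        frame = reference.load_farm_summary()
        summary = study_summary(frame)
        assert summary["n_cows_total"] == 3003
        assert round(summary["mean_cows_per_farm"]) == 104
        assert summary["n_farms"] == 29

    def test_single_farm_summary_equals_that_farm(self, study_farms,
                                                  default_engine):
        _, farms = study_farms
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            audit, _ = audit_farm(farms[0], default_engine)
        summary = study_summary([audit])
        assert summary["replaced_loss_total"] == pytest.approx(
            audit.replaced_loss)
        assert summary["replacement_rate_mean"] == pytest.approx(
            audit.replacement_rate)
        assert summary["n_cows_total"] == audit.n_cows
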