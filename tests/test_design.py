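"""Trial state machine: recommendation, stopping rules, enrolment gating, delay."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from titecrm import (
    DesignConfig,
    PosteriorSummary,
    SequencingError,
    StopReason,
    TrialState,
    ValidationError,
    assign_with_delay,
    enrolment_gate,
    evaluate_stopping,
    select_schedule,
)
from titecrm.design import PendingPatient, RUN_IN_CONCURRENT

from conftest import TTL, WINDOW, make_record


def summary(p_hat, exceed=None):
    p = np.asarray(p_hat, dtype=float)
    e = np.asarray(exceed, dtype=float) if exceed is not None else np.linspace(0.1, 0.6, p.size)
    return PosteriorSummary(param_mean=0.0, param_sd=1.0, p_hat=p, exceed=e, n_eval=1)


def state_with(n_records=0, schedules=(), highest=0, now=0.0, last_start=None):
    st_ = TrialState(now=now)
    for i, s in enumerate(schedules):
        st_.add_record(make_record(i + 1, s, WINDOW, enrol=0.0))
    if not schedules:
        st_.highest_tried = highest
    st_.last_start = last_start if last_start is not None else st_.last_start
    return st_


@pytest.fixture
def design():
    return DesignConfig(ttl=TTL, max_n=25, window=WINDOW)


class TestSelectSchedule:
    def test_closest_not_above(self, design):
        post = summary([0.05, 0.10, 0.20, 0.35, 0.50, 0.60])
        state = state_with(highest=6)
        assert select_schedule(post, state, design) == 3

    def test_no_skipping_untried(self, design):
        # model wants 4 but only schedules up to 2 have been tried
        post = summary([0.05, 0.10, 0.20, 0.26, 0.50, 0.60])
        state = state_with(highest=2)
        assert select_schedule(post, state, design) == 3

    def test_unrestricted_deescalation(self, design):
        post = summary([0.24, 0.40, 0.55, 0.65, 0.75, 0.85])
        state = state_with(highest=4)
        assert select_schedule(post, state, design) == 1

    def test_overdose_gate_caps_choice(self):
        design = DesignConfig(ttl=TTL, max_n=25, window=WINDOW, overdose_gate=0.25)
        post = summary([0.05, 0.10, 0.20, 0.26, 0.5, 0.6],
                       exceed=[0.01, 0.05, 0.30, 0.60, 0.9, 0.95])
        state = state_with(highest=6)
        # model choice 3 but its exceedance 0.30 >= gate 0.25 -> capped at 2
        assert select_schedule(post, state, design) == 2

    def test_all_too_toxic_falls_to_lowest(self, design):
        post = summary([0.60, 0.70, 0.80, 0.85, 0.90, 0.95])
        state = state_with(highest=3)
        assert select_schedule(post, state, design) == 1

    @given(
        phat0=st.floats(min_value=0.01, max_value=0.5),
        spread=st.floats(min_value=0.01, max_value=0.09),
        highest=st.integers(min_value=0, max_value=6),
    )
    @settings(derandomize=True, max_examples=100)
    def test_never_skips_on_escalation(self, phat0, spread, highest):
        design = DesignConfig(ttl=TTL, max_n=25, window=WINDOW)
        p = np.clip(phat0 + spread * np.arange(6), 1e-4, 1 - 1e-4)
        post = summary(p)
        state = state_with(highest=highest)
        assert select_schedule(post, state, design) <= max(highest + 1, 1)


class TestEvaluateStopping:
    def test_safety_when_lowest_exceeds(self, design):
        post = summary([0.4, 0.5, 0.6, 0.7, 0.8, 0.9],
                       exceed=[0.97, 0.98, 0.99, 0.99, 1.0, 1.0])
        assert evaluate_stopping(post, state_with(schedules=[1, 1]), design) is StopReason.SAFETY

    def test_success_after_m_on_recommended(self):
        design = DesignConfig(ttl=TTL, max_n=25, window=WINDOW, success_m=8)
        post = summary([0.05, 0.24, 0.40, 0.55, 0.65, 0.75],
                       exceed=[0.01, 0.3, 0.7, 0.9, 0.95, 0.99])
        state = state_with(schedules=[1, 1, 1] + [2] * 8)
        assert evaluate_stopping(post, state, design) is StopReason.SUCCESS

    def test_below_cap_continues(self, design):
        post = summary([0.05, 0.10, 0.20, 0.26, 0.5, 0.6])
        state = state_with(schedules=[1] * 14)
        design15 = DesignConfig(ttl=TTL, max_n=15, window=WINDOW)
        assert evaluate_stopping(post, state, design15) is StopReason.NONE

    def test_max_n_reached(self, design):
        post = summary([0.05, 0.10, 0.20, 0.26, 0.5, 0.6])
        state = state_with(schedules=[1] * 25)
        assert evaluate_stopping(post, state, design) is StopReason.MAX_N

    def test_safety_takes_precedence(self):
        design = DesignConfig(ttl=TTL, max_n=5, window=WINDOW, success_m=2)
        post = summary([0.4, 0.5, 0.6, 0.7, 0.8, 0.9],
                       exceed=[0.97, 0.98, 0.99, 0.99, 1.0, 1.0])
        state = state_with(schedules=[1] * 6)
        assert evaluate_stopping(post, state, design) is StopReason.SAFETY

    def test_stop_is_sticky(self, design):
        post = summary([0.05, 0.10, 0.20, 0.26, 0.5, 0.6])
        state = state_with(schedules=[1, 2])
        state.stop = StopReason.SAFETY
        assert evaluate_stopping(post, state, design) is StopReason.SAFETY

    def test_safety_monotone_in_dlts(self, grid6, design):
        # adding DLTs at the lowest schedule never turns a safety stop into a continue
        from titecrm import posterior_by_quadrature

        recs = [make_record(i + 1, 1, WINDOW, dlt=1, t_dlt=3.0) for i in range(4)]
        state = TrialState()
        for r in recs:
            state.add_record(r)
        post = posterior_by_quadrature(recs, grid6, TTL)
        base = evaluate_stopping(post, state, design)
        more = recs + [make_record(9, 1, WINDOW, dlt=1, t_dlt=3.0)]
        state2 = TrialState()
        for r in more:
            state2.add_record(r)
        post2 = posterior_by_quadrature(more, grid6, TTL)
        worse = evaluate_stopping(post2, state2, design)
        if base is StopReason.SAFETY:
            assert worse is StopReason.SAFETY


class TestEnrolmentGate:
    def test_run_in_blocks_until_fully_observed(self, design):
        state = TrialState(now=6.0)
        state.add_record(make_record(1, 1, 6.0, enrol=0.0))  # only 6 of 12 weeks observed
        state.add_record(make_record(2, 1, 0.0, enrol=6.0))
        allowed, slots = enrolment_gate(state, design, now=6.0)
        assert (allowed, slots) == (False, 0)

    def test_two_slots_after_gap(self, design):
        state = TrialState(now=45.0)
        for i in range(3):
            state.add_record(make_record(i + 1, 1, WINDOW, enrol=i * 13.0))
        # last start at week 26, fully observed by 38; query at 45: gap of 19 > 4
        allowed, slots = enrolment_gate(state, design, now=45.0)
        assert (allowed, slots) == (True, 2)

    def test_single_slot_occupied(self, design):
        state = TrialState(now=40.0)
        for i in range(3):
            state.add_record(make_record(i + 1, 1, WINDOW, enrol=i * 13.0))
        state.add_record(make_record(4, 2, 1.0, enrol=39.0))  # started 1 week ago
        allowed, slots = enrolment_gate(state, design, now=40.0)
        assert (allowed, slots) == (False, 0)

    def test_concurrent_run_in_policy(self):
        design = DesignConfig(ttl=TTL, max_n=25, window=WINDOW,
                              run_in_policy=RUN_IN_CONCURRENT)
        state = TrialState(now=1.0)
        state.add_record(make_record(1, 1, 1.0, enrol=0.0))
        allowed, slots = enrolment_gate(state, design, now=1.0)
        assert allowed and slots == 2


class TestAssignWithDelay:
    def test_zero_delay_matches_select_schedule(self, design):
        post = summary([0.05, 0.10, 0.20, 0.26, 0.5, 0.6])
        state = state_with(schedules=[1, 1, 1], now=30.0)
        state.pending.append(PendingPatient(id="P9", enrol_time=30.0))
        rec = assign_with_delay(state, design, post)
        expect = select_schedule(post, state_with(schedules=[1, 1, 1]), design)
        assert rec.schedule == expect
        assert not state.pending

    def test_six_week_delay_uses_decision_time(self):
        design = DesignConfig(ttl=TTL, max_n=25, window=WINDOW, assignment_delay=6.0)
        post = summary([0.05, 0.10, 0.20, 0.26, 0.5, 0.6])
        state = state_with(schedules=[1, 1, 1], now=16.0)
        state.pending.append(PendingPatient(id="P9", enrol_time=10.0))
        rec = assign_with_delay(state, design, post)
        assert rec.enrol_time == 10.0
        assert rec.follow_up == pytest.approx(6.0)  # backbone weeks count

    def test_fifo_order(self):
        design = DesignConfig(ttl=TTL, max_n=25, window=WINDOW, assignment_delay=6.0)
        post = summary([0.05, 0.10, 0.20, 0.26, 0.5, 0.6])
        state = state_with(schedules=[1, 1, 1], now=30.0)
        state.pending.extend([PendingPatient(id="B", enrol_time=12.0),
                              PendingPatient(id="A", enrol_time=10.0)])
        rec = assign_with_delay(state, design, post)
        assert rec.id == "A"

    def test_sequencing_error_before_delay(self):
        design = DesignConfig(ttl=TTL, max_n=25, window=WINDOW, assignment_delay=6.0)
        post = summary([0.05, 0.10, 0.20, 0.26, 0.5, 0.6])
        state = state_with(schedules=[1, 1, 1], now=12.0)
        state.pending.append(PendingPatient(id="P9", enrol_time=10.0))
        with pytest.raises(SequencingError):
            assign_with_delay(state, design, post)


class TestDesignConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(ttl=1.5, max_n=25, window=WINDOW),
            dict(ttl=TTL, max_n=2, window=WINDOW, run_in_n=3),
            dict(ttl=TTL, max_n=25, window=WINDOW, slot_gap=0.0),
            dict(ttl=TTL, max_n=25, window=WINDOW, cohort_size=0),
            dict(ttl=TTL, max_n=25, window=WINDOW, run_in_policy="bogus"),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            DesignConfig(**kwargs)
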