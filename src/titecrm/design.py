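"""Trial state machine: schedule recommendation, stopping rules, enrolment gating.

Encodes the escalation and enrolment conventions of a schedule-finding
TiTE-CRM trial run with cohorts of one:

* the recommended schedule is the one estimated closest to, but not above,
  the maximum tolerated schedule (highest schedule with fitted DLT
  probability at or below the target toxicity level);
* no schedule skipping when escalating to untried schedules; de-escalation
  is never restricted; optionally, an overdose-control gate excludes
  schedules whose posterior probability of exceeding the TTL is too high;
* a run-in of patients treated at the lowest schedule before any
  model-based allocation, recruitment slots that pace concurrent starts,
  and an optional delay between enrolment and schedule assignment (for a
  stage in which every patient receives the same backbone treatment for
  the first weeks);
* three stopping rules — safety (lowest schedule too toxic), success
  (stabilisation of the MTD estimate) and maximum sample size — with
  precedence safety > success > max_n, and stop reasons that are sticky.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import List, Optional

import numpy as np

from .errors import SequencingError, ValidationError
from .model import DEFAULT_PRIOR_SD, PatientRecord, PosteriorSummary

RUN_IN_SEQUENTIAL = "sequential-full-observation"
RUN_IN_CONCURRENT = "concurrent-then-wait"


class StopReason(str, Enum):
    NONE = "none"
    SAFETY = "safety"
    SUCCESS = "success"
    MAX_N = "max_n"


@dataclass(frozen=True)
class DesignConfig:
    """Design parameters of one trial stage.

    Parameters
    ----------
    ttl
        Target toxicity level, the acceptable DLT probability.
    max_n
        Maximum sample size.
    window
        DLT assessment window in weeks.
    success_m
        Stop for success once this many patients have been assigned to the
        currently recommended schedule; ``None`` disables early stopping.
    safety_threshold
        Stop for safety when the posterior probability that the lowest
        schedule's DLT rate exceeds the TTL passes this value.
    overdose_gate
        When set, schedules whose exceedance probability is at or above
        this value are ineligible for assignment ("no overdosing"); the
        conventional value when enabled is 0.25.  ``None`` disables it.
    no_skip
        Forbid skipping untried schedules on escalation.
    run_in_n, run_in_policy
        Number of run-in patients treated at the lowest schedule, and
        whether they are enrolled strictly sequentially with full
        observation between them, or concurrently with a wait afterwards.
    slot_gap
        Weeks since the previous treatment start after which a second
        recruitment slot opens.
    assignment_delay
        Weeks between enrolment and schedule assignment (0 for stages
        without a common backbone period; 6 for a stage whose patients all
        receive the same treatment for the first 6 weeks).
    cohort_size
        Patients per allocation decision; the design uses cohorts of one.
    prior_sd
        Prior standard deviation of the model parameter.
    """

    ttl: float
    max_n: int
    window: float
    success_m: Optional[int] = None
    safety_threshold: float = 0.95
    overdose_gate: Optional[float] = None
    no_skip: bool = True
    run_in_n: int = 3
    run_in_policy: str = RUN_IN_SEQUENTIAL
    slot_gap: float = 4.0
    assignment_delay: float = 0.0
    cohort_size: int = 1
    prior_sd: float = DEFAULT_PRIOR_SD

    def __post_init__(self) -> None:
        if not (0.0 < self.ttl < 1.0):
            raise ValidationError(f"ttl must lie in (0,1): {self.ttl}")
        if not (self.max_n >= self.run_in_n >= 0):
            raise ValidationError("need max_n >= run_in_n >= 0")
        if not (0.0 < self.safety_threshold < 1.0):
            raise ValidationError("safety_threshold must lie in (0,1)")
        if self.overdose_gate is not None and not (0.0 < self.overdose_gate < 1.0):
            raise ValidationError("overdose_gate must lie in (0,1) or be None")
        if self.slot_gap <= 0:
            raise ValidationError("slot_gap must be positive")
        if self.cohort_size < 1:
            raise ValidationError("cohort_size must be >= 1")
        if self.window <= 0:
            raise ValidationError("window must be positive")
        if self.assignment_delay < 0:
            raise ValidationError("assignment_delay must be non-negative")
        if self.run_in_policy not in (RUN_IN_SEQUENTIAL, RUN_IN_CONCURRENT):
            raise ValidationError(
                f"run_in_policy must be '{RUN_IN_SEQUENTIAL}' or '{RUN_IN_CONCURRENT}'"
            )
        if self.success_m is not None and self.success_m < 1:
            raise ValidationError("success_m must be >= 1 or None")


@dataclass(frozen=True)
class PendingPatient:
    """A patient enrolled (treatment started) but awaiting schedule assignment."""

    id: str
    enrol_time: float


@dataclass
class TrialState:
    """Mutable calendar-time state of one running trial."""

    now: float = 0.0
    records: List[PatientRecord] = field(default_factory=list)
    pending: List[PendingPatient] = field(default_factory=list)
    highest_tried: int = 0  # 0 = nothing assigned yet; schedules are 1-based
    stop: StopReason = StopReason.NONE
    last_start: Optional[float] = None

    def advance(self, now: float) -> None:
        if now < self.now:
            raise SequencingError(f"time cannot move backwards ({now} < {self.now})")
        self.now = now

    def add_record(self, record: PatientRecord) -> None:
        self.records.append(record)
        self.highest_tried = max(self.highest_tried, record.schedule)
        start = record.enrol_time
        self.last_start = start if self.last_start is None else max(self.last_start, start)

    @property
    def n_enrolled(self) -> int:
        return len(self.records) + len(self.pending)


def select_schedule(
    posterior: PosteriorSummary,
    state: TrialState,
    design: DesignConfig,
) -> int:
    """Recommend the next treatment schedule (1-based index).

    The model choice is the estimated maximum tolerated schedule: the one
    whose fitted DLT probability is closest to the TTL, ties broken to the
    lower schedule (the standard CRM estimator; with a monotone fit this
    is never above the schedule whose rate matches the TTL).  Escalation
    is then capped at ``highest_tried + 1`` when skipping is forbidden,
    and — when the overdose gate is active — at the highest schedule
    whose exceedance probability is below the gate.  De-escalation is
    never restricted.
    """
    n = posterior.n_schedules
    if n < 1:
        raise ValidationError("posterior covers no schedules")
    dist = np.abs(posterior.p_hat - design.ttl)
    choice = int(np.argmin(dist)) + 1  # argmin takes the first (lower) on ties
    if design.no_skip and choice > state.highest_tried:
        choice = min(choice, max(state.highest_tried + 1, 1))
    if design.overdose_gate is not None:
        safe = [s for s in range(1, n + 1) if posterior.exceed[s - 1] < design.overdose_gate]
        cap = max(safe) if safe else 1
        choice = min(choice, cap)
    return choice


def evaluate_stopping(
    posterior: PosteriorSummary,
    state: TrialState,
    design: DesignConfig,
) -> StopReason:
    """Evaluate the three stopping rules; precedence safety > success > max_n.

    Safety: posterior probability that the lowest schedule's DLT rate
    exceeds the TTL is above the safety threshold.  Success: ``success_m``
    patients have already been assigned to the currently recommended
    schedule (stabilisation of the MTD estimate).  Max-n: the sample size
    cap is reached.  A stop reason already recorded on the state is sticky.
    """
    if state.stop is not StopReason.NONE:
        return state.stop
    if posterior.n_schedules < 1:
        raise ValidationError("posterior covers no schedules")
    if posterior.exceed[0] > design.safety_threshold:
        return StopReason.SAFETY
    if design.success_m is not None and state.records:
        recommended = select_schedule(posterior, state, design)
        n_on_rec = sum(1 for r in state.records if r.schedule == recommended)
        if n_on_rec >= design.success_m:
            return StopReason.SUCCESS
    if len(state.records) >= design.max_n:
        return StopReason.MAX_N
    return StopReason.NONE


def _occupied_slots(state: TrialState, design: DesignConfig, now: float) -> int:
    """Patients holding a recruitment slot: started within the last slot_gap weeks."""
    starts = [r.enrol_time for r in state.records] + [p.enrol_time for p in state.pending]
    return sum(1 for s in starts if s <= now and now - s <= design.slot_gap)


def enrolment_gate(
    state: TrialState,
    design: DesignConfig,
    now: float,
) -> tuple[bool, int]:
    """May a new patient enrol at calendar time ``now``, and how many slots are open?

    During the run-in (fewer than ``run_in_n`` patients): under the
    sequential policy enrolment is allowed only when every existing run-in
    patient has been observed for the full DLT window; under the
    concurrent policy run-in patients may enrol freely.  Run-in gating
    takes precedence over slot accounting, and at most one run-in patient
    enrols per decision under the sequential policy.

    After the run-in, enrolment requires all run-in patients to be fully
    observed, and the slot rule applies: two slots exist when more than
    ``slot_gap`` weeks have passed since the previous treatment start,
    otherwise one; slots held by recently started patients are subtracted.
    """
    if now < state.now:
        raise SequencingError("gate queried in the past")
    n = state.n_enrolled
    run_in = [r for r in state.records[: design.run_in_n]]

    def fully_observed(rec: PatientRecord) -> bool:
        return min(now - rec.enrol_time, rec.window) >= rec.window - 1e-9

    if n < design.run_in_n:
        if design.run_in_policy == RUN_IN_SEQUENTIAL:
            ok = all(fully_observed(r) for r in run_in) and not state.pending
            return (ok, 1 if ok else 0)
        return (True, design.run_in_n - n)

    if not all(fully_observed(r) for r in run_in):
        return (False, 0)

    base = 2 if (state.last_start is not None and now - state.last_start > design.slot_gap) else 1
    open_slots = max(base - _occupied_slots(state, design, now), 0)
    return (open_slots > 0, open_slots)


def assign_with_delay(
    state: TrialState,
    design: DesignConfig,
    posterior_at_decision_time: PosteriorSummary,
) -> PatientRecord:
    """Assign a schedule to the oldest pending patient whose delay has elapsed.

    Pending patients are processed in enrolment order (FIFO).  The
    decision uses the posterior computed from data observed at the
    decision time (enrolment + assignment_delay); the returned record's
    follow-up clock starts at enrolment, so the backbone period counts
    towards the DLT window.  The caller supplies the patient's observed
    outcome afterwards; the record is created DLT-free with zero revealed
    follow-up beyond the decision time.
    """
    due = [p for p in state.pending if p.enrol_time + design.assignment_delay <= state.now + 1e-9]
    if not due:
        raise SequencingError("no pending patient whose assignment delay has elapsed")
    patient = min(due, key=lambda p: p.enrol_time)
    schedule = select_schedule(posterior_at_decision_time, state, design)
    state.pending.remove(patient)
    record = PatientRecord(
        id=patient.id,
        enrol_time=patient.enrol_time,
        schedule=schedule,
        window=design.window,
        follow_up=min(max(state.now - patient.enrol_time, 0.0), design.window),
        dlt=0,
        t_dlt=None,
    )
    state.add_record(record)
    return record
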