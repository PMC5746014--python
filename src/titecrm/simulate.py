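"""Event-driven virtual trial replication and operating-characteristics studies.

A replicate draws patient arrivals from an accrual process, runs the
enrolment gate / schedule-selection / stopping machinery of the design
engine on calendar time, reveals each patient's (latent) toxicity outcome
only as follow-up accrues, and refreshes the model posterior at every
allocation decision.  Replicates are fully reproducible from their seed;
the operating-characteristics driver derives replicate seeds
deterministically from a master seed (``seed_i = master_seed + i``),
enabling common-random-number comparisons across scenarios and designs.

The posterior backend inside simulation is the deterministic quadrature;
the MCMC backend exists as a cross-check and would only add Monte-Carlo
noise here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .design import (
    RUN_IN_CONCURRENT,
    RUN_IN_SEQUENTIAL,
    DesignConfig,
    StopReason,
    TrialState,
    enrolment_gate,
    evaluate_stopping,
    select_schedule,
)
from .errors import ValidationError
from .model import PatientRecord, PosteriorSummary, ScheduleGrid, posterior_by_quadrature

DIST_UNIFORM = "uniform"
DIST_TRIANGULAR = "triangular-midmode"

ARRIVALS_EXPONENTIAL = "exponential"
ARRIVALS_FIXED = "fixed-interval"

_EPS = 1e-9  # calendar nudge so strict "more than slot_gap weeks" comparisons pass


@dataclass(frozen=True)
class Scenario:
    """Simulation ground truth for one scenario.

    ``true_p`` are the true per-schedule DLT probabilities (monotone
    non-decreasing unless ``allow_non_monotone``); ``dlt_time_dist`` is the
    distribution of the time from treatment start to DLT within the
    assessment window (flat, or triangular with the mode half-way through
    the window); ``accrual_rate`` is in patients per week (e.g. 1/4, 1/6,
    1/8).
    """

    true_p: tuple[float, ...]
    dlt_time_dist: str = DIST_UNIFORM
    accrual_rate: float = 0.25
    window: float = 12.0
    arrival_process: str = ARRIVALS_EXPONENTIAL
    allow_non_monotone: bool = False
    name: str = "scenario"

    def __post_init__(self) -> None:
        p = tuple(float(x) for x in self.true_p)
        object.__setattr__(self, "true_p", p)
        if any(not (0.0 <= x <= 1.0) for x in p):
            raise ValidationError("true_p values must lie in [0,1]")
        if not self.allow_non_monotone and any(b < a for a, b in zip(p, p[1:])):
            raise ValidationError(
                "true_p must be non-decreasing (set allow_non_monotone for "
                "deliberately non-monotone scenarios)"
            )
        if self.accrual_rate <= 0:
            raise ValidationError("accrual_rate must be positive")
        if self.window <= 0:
            raise ValidationError("window must be positive")
        if self.dlt_time_dist not in (DIST_UNIFORM, DIST_TRIANGULAR):
            raise ValidationError(f"unknown dlt_time_dist: {self.dlt_time_dist!r}")
        if self.arrival_process not in (ARRIVALS_EXPONENTIAL, ARRIVALS_FIXED):
            raise ValidationError(f"unknown arrival_process: {self.arrival_process!r}")


@dataclass(frozen=True)
class TrialResult:
    """Outcome of a single simulated trial replicate."""

    selected: Optional[int]  # recommended MTD schedule (1-based), None if none declared safe
    stop_reason: StopReason
    n: int
    duration: float
    alloc: tuple[int, ...]
    dlts: tuple[int, ...]
    seed: Optional[int]

    def __post_init__(self) -> None:
        if sum(self.alloc) != self.n:
            raise ValidationError("allocation must sum to the sample size")
        if any(d > a for d, a in zip(self.dlts, self.alloc)):
            raise ValidationError("DLT counts cannot exceed allocations")
        if self.duration < 0:
            raise ValidationError("duration must be non-negative")


def sample_time_to_dlt(dist: str, window: float, rng: np.random.Generator) -> float:
    """Draw a time-to-DLT (weeks) supported on [0, window]."""
    if window <= 0:
        raise ValidationError("window must be positive")
    if dist == DIST_UNIFORM:
        return float(rng.uniform(0.0, window))
    if dist == DIST_TRIANGULAR:
        return float(rng.triangular(0.0, window / 2.0, window))
    raise ValidationError(f"unknown time-to-DLT distribution: {dist!r}")


def sample_patient(
    true_p_s: float,
    dist: str,
    window: float,
    rng: np.random.Generator,
) -> tuple[int, Optional[float]]:
    """Draw one patient's latent outcome: DLT indicator and, if toxic, its timing."""
    if not (0.0 <= true_p_s <= 1.0):
        raise ValidationError("true_p_s must lie in [0,1]")
    dlt = int(rng.random() < true_p_s)
    if dlt:
        return 1, sample_time_to_dlt(dist, window, rng)
    return 0, None


def sample_arrivals(
    rate: float,
    horizon: float,
    rng: np.random.Generator,
    process: str = ARRIVALS_EXPONENTIAL,
) -> list[float]:
    """Enrolment-opportunity times on (0, horizon], strictly increasing.

    Exponential inter-arrivals with mean ``1/rate`` by default (a Poisson
    accrual process); a deterministic fixed-interval mode gives times
    ``1/rate, 2/rate, ...`` for debugging.
    """
    if rate <= 0:
        raise ValidationError("rate must be positive")
    times: list[float] = []
    t = 0.0
    while True:
        if process == ARRIVALS_EXPONENTIAL:
            t += float(rng.exponential(1.0 / rate))
        elif process == ARRIVALS_FIXED:
            t += 1.0 / rate
        else:
            raise ValidationError(f"unknown arrival process: {process!r}")
        if t > horizon:
            return times
        times.append(t)


@dataclass
class _VirtualPatient:
    id: str
    start: float
    schedule: Optional[int] = None  # None while awaiting delayed assignment
    dlt: int = 0
    t_dlt: Optional[float] = None

    def revealed(self, now: float, window: float) -> Optional[PatientRecord]:
        if self.schedule is None or self.start > now + _EPS:
            return None
        fu = min(max(now - self.start, 0.0), window)
        if self.dlt and self.t_dlt is not None and self.t_dlt <= fu + _EPS:
            return PatientRecord(
                id=self.id, enrol_time=self.start, schedule=self.schedule,
                window=window, follow_up=fu, dlt=1, t_dlt=min(self.t_dlt, fu),
            )
        return PatientRecord(
            id=self.id, enrol_time=self.start, schedule=self.schedule,
            window=window, follow_up=fu, dlt=0, t_dlt=None,
        )


class _ArrivalStream:
    """Lazy renewal-process arrival generator."""

    def __init__(self, scenario: Scenario, rng: np.random.Generator) -> None:
        self._scenario = scenario
        self._rng = rng
        self._t = 0.0

    def next(self) -> float:
        if self._scenario.arrival_process == ARRIVALS_FIXED:
            self._t += 1.0 / self._scenario.accrual_rate
        else:
            self._t += float(self._rng.exponential(1.0 / self._scenario.accrual_rate))
        return self._t


def _state_at(patients: Sequence[_VirtualPatient], now: float, window: float) -> TrialState:
    """Reconstruct the observable trial state at calendar time ``now``."""
    from .design import PendingPatient

    state = TrialState(now=now)
    for p in patients:
        rec = p.revealed(now, window)
        if rec is not None:
            state.add_record(rec)
        elif p.start <= now + _EPS:
            state.pending.append(PendingPatient(id=p.id, enrol_time=p.start))
            state.last_start = p.start if state.last_start is None else max(state.last_start, p.start)
    return state


def _gate_open_time(patients: Sequence[_VirtualPatient], design: DesignConfig,
                    window: float, after: float) -> float:
    """Earliest time >= ``after`` at which the enrolment gate opens."""
    n = len(patients)
    if n < design.run_in_n:
        if design.run_in_policy == RUN_IN_CONCURRENT:
            return after
        # sequential: wait until every existing run-in patient completes follow-up
        t_ready = max((p.start + window for p in patients), default=after)
        return max(after, t_ready)
    run_in_done = max((p.start + window for p in patients[: design.run_in_n]), default=after)
    last_start = max((p.start for p in patients), default=None)
    slot_ready = after if last_start is None else last_start + design.slot_gap + _EPS
    return max(after, run_in_done, slot_ready)


def simulate_trial(
    scenario: Scenario,
    design: DesignConfig,
    grid: ScheduleGrid,
    seed: Optional[int] = None,
    posterior_fn=None,
) -> TrialResult:
    """Run one virtual trial and return its outcome.

    Event-driven: arrivals come from the scenario's accrual process;
    each enrolment waits for the gate (run-in observation, recruitment
    slots); the posterior is refreshed from the data revealed at each
    decision time; stopping rules are checked before every enrolment and
    at the final analysis.  When a delayed-assignment design is used the
    schedule decision for each patient is made ``assignment_delay`` weeks
    after treatment start, on the data observed then.

    The final MTD is the model recommendation on the complete data after
    all patients finish follow-up, capped at the highest schedule actually
    tried; a safety stop declares no schedule safe.
    """
    if len(scenario.true_p) != grid.n_schedules:
        raise ValidationError(
            f"scenario has {len(scenario.true_p)} schedules, grid has {grid.n_schedules}"
        )
    if abs(scenario.window - design.window) > 1e-9:
        raise ValidationError("scenario and design windows differ")
    if posterior_fn is None:
        def posterior_fn(records):
            return posterior_by_quadrature(records, grid, design.ttl, prior_sd=design.prior_sd)

    rng = np.random.default_rng(seed)
    arrivals = _ArrivalStream(scenario, rng)
    patients: List[_VirtualPatient] = []
    window = design.window
    stop = StopReason.NONE
    stop_time: Optional[float] = None
    # Buffer of drawn arrival times not yet enrolled; patients queue until
    # the gate opens.  The buffer always holds at least one future arrival.
    buffer: List[float] = [arrivals.next()]

    def ensure_arrival_beyond(t: float) -> None:
        while buffer[-1] <= t:
            buffer.append(arrivals.next())

    def reveal(now: float) -> TrialState:
        return _state_at(patients, now, window)

    def assign_outcome(p: _VirtualPatient, schedule: int) -> None:
        # one uniform + one timing draw per patient, drawn unconditionally,
        # keeps random streams aligned across scenarios sharing a seed
        # (common random numbers for paired design comparisons)
        p.schedule = schedule
        u = rng.random()
        t = sample_time_to_dlt(scenario.dlt_time_dist, window, rng)
        p.dlt = int(u < scenario.true_p[schedule - 1])
        p.t_dlt = t if p.dlt else None

    def process_due_assignments(upto: float) -> None:
        """Stage-B style delayed assignments, FIFO at each due time."""
        if design.assignment_delay <= 0:
            return
        while True:
            due = [p for p in patients
                   if p.schedule is None and p.start + design.assignment_delay <= upto + _EPS]
            if not due:
                return
            p = min(due, key=lambda q: q.start)
            t_dec = p.start + design.assignment_delay
            state = reveal(t_dec)
            post = posterior_fn(state.records)
            assign_outcome(p, select_schedule(post, state, design))

    while len(patients) < design.max_n:
        enrol_t = _gate_open_time(patients, design, window, buffer[0])
        ensure_arrival_beyond(enrol_t)
        process_due_assignments(enrol_t)
        state = reveal(enrol_t)
        post = posterior_fn(state.records)
        stop = evaluate_stopping(post, state, design)
        if stop is not StopReason.NONE:
            stop_time = enrol_t
            break

        _, open_slots = enrolment_gate(state, design, enrol_t)
        n_waiting = sum(1 for a in buffer if a <= enrol_t)
        k = min(max(open_slots, 1), n_waiting, design.max_n - len(patients))
        for _ in range(k):
            buffer.pop(0)
            p = _VirtualPatient(id=f"P{len(patients) + 1:03d}", start=enrol_t)
            if len(patients) < design.run_in_n:
                assign_outcome(p, 1)
            elif design.assignment_delay > 0:
                p.schedule = None  # decided assignment_delay weeks later
            else:
                assign_outcome(p, select_schedule(post, state, design))
            patients.append(p)
            if p.schedule is not None:
                state.add_record(p.revealed(enrol_t, window))  # updates highest_tried
            if len(patients) <= design.run_in_n and design.run_in_policy == RUN_IN_SEQUENTIAL:
                break  # sequential run-in: one patient per fully observed predecessor

    # Final analysis on complete follow-up of everyone enrolled.
    if patients:
        process_due_assignments(max(p.start for p in patients) + design.assignment_delay)
        t_end = max(p.start + window for p in patients)
    else:
        t_end = 0.0
    if stop is StopReason.NONE:
        stop = StopReason.MAX_N
        stop_time = None
    duration = stop_time if (stop is StopReason.SAFETY and stop_time is not None) else t_end

    alloc = [0] * grid.n_schedules
    dlts = [0] * grid.n_schedules
    for p in patients:
        if p.schedule is None:
            continue
        alloc[p.schedule - 1] += 1
        if p.dlt:
            dlts[p.schedule - 1] += 1

    if stop is StopReason.SAFETY:
        selected: Optional[int] = None
    else:
        final_state = reveal(t_end)
        final_post = posterior_fn(final_state.records)
        # safety can still show at the final look
        if final_post.exceed[0] > design.safety_threshold:
            stop, selected = StopReason.SAFETY, None
        else:
            selected = min(select_schedule(final_post, final_state, design),
                           max(final_state.highest_tried, 1))

    return TrialResult(
        selected=selected,
        stop_reason=stop,
        n=sum(alloc),
        duration=float(duration),
        alloc=tuple(alloc),
        dlts=tuple(dlts),
        seed=seed,
    )


def run_oc_study(
    scenarios: Sequence[Scenario],
    designs: Sequence[DesignConfig],
    grid: ScheduleGrid,
    n_rep: int = 1000,
    master_seed: int = 0,
    design_names: Optional[Sequence[str]] = None,
):
    """Replicate every scenario x design cell and aggregate operating characteristics.

    Replicate ``i`` of every cell uses seed ``master_seed + i`` (common
    random numbers across cells).  Returns an
    :class:`~titecrm.reporting.OCTable`.
    """
    from .reporting import OCTable, aggregate_results

    if n_rep < 1:
        raise ValidationError("n_rep must be >= 1")
    names = list(design_names) if design_names else [f"design{j + 1}" for j in range(len(designs))]
    rows = []
    for scenario in scenarios:
        for dname, design in zip(names, designs):
            results = [
                simulate_trial(scenario, design, grid, seed=master_seed + i)
                for i in range(n_rep)
            ]
            cell = aggregate_results(results)
            cell.scenario = scenario.name
            cell.design = dname
            rows.append(cell)
    return OCTable(cells=rows, n_rep=n_rep, master_seed=master_seed,
                   n_schedules=grid.n_schedules)
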