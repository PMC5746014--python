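import numpy as np
import pytest

from titecrm import DesignConfig, PatientRecord, Scenario, ScheduleGrid

SKELETON_6 = (0.05, 0.10, 0.15, 0.25, 0.35, 0.45)
TTL = 0.25
WINDOW = 12.0


def make_record(i, schedule, follow_up, dlt=0, t_dlt=None, enrol=0.0, window=WINDOW):
    return PatientRecord(
        id=f"P{i:03d}", enrol_time=enrol, schedule=schedule, window=window,
        follow_up=follow_up, dlt=dlt, t_dlt=t_dlt,
    )


@pytest.fixture
def grid6():
    return ScheduleGrid(skeleton=SKELETON_6)


@pytest.fixture
def design_a1():
    return DesignConfig(ttl=TTL, max_n=25, window=WINDOW)


@pytest.fixture
def scenario_skeleton_true(grid6):
    return Scenario(true_p=grid6.skeleton, accrual_rate=0.25, window=WINDOW,
                    name="skeleton-true")


@pytest.fixture
def full_records_10():
    """Ten patients all fully followed up (every weight 1): the binary-CRM limit."""
    spec = [(1, 0), (1, 0), (1, 0), (2, 0), (2, 1), (3, 0), (3, 1), (4, 0), (4, 1), (4, 1)]
    return [
        make_record(i + 1, s, WINDOW, dlt=d, t_dlt=2.0 + 0.5 * i if d else None)
        for i, (s, d) in enumerate(spec)
    ]


@pytest.fixture
def partial_records_10():
    """Ten patients with a mix of full, partial and toxic follow-up."""
    spec = [
        (1, 12.0, 0, None), (1, 12.0, 0, None), (1, 12.0, 0, None),
        (2, 9.0, 0, None), (2, 12.0, 1, 7.5), (3, 6.0, 0, None),
        (3, 3.0, 1, 2.0), (4, 4.5, 0, None), (4, 12.0, 1, 10.0), (4, 1.5, 0, None),
    ]
    return [
        make_record(i + 1, s, fu, dlt=d, t_dlt=t)
        for i, (s, fu, d, t) in enumerate(spec)
    ]
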