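"""Live schedule recommendation from accumulated patient data.

The core use case during trial conduct: given the design and every
patient's current follow-up (including partially observed ones), refit
the dose-toxicity model and print the schedule to assign next.
"""

import numpy as np

from titecrm import (
    DesignConfig,
    PatientRecord,
    ScheduleGrid,
    TrialState,
    evaluate_stopping,
    posterior_by_quadrature,
    select_schedule,
)

grid = ScheduleGrid(skeleton=(0.05, 0.10, 0.15, 0.25, 0.35, 0.45))
design = DesignConfig(ttl=0.25, max_n=25, window=12.0)

# Six patients so far: the three run-in patients fully observed at the
# lowest schedule, then escalation, with the latest two only partially
# followed up (9 and 3 of the 12-week DLT window).
patients = [
    PatientRecord("P001", 0.0, 1, 12.0, 12.0),
    PatientRecord("P002", 12.0, 1, 12.0, 12.0),
    PatientRecord("P003", 24.0, 1, 12.0, 12.0),
    PatientRecord("P004", 36.0, 2, 12.0, 12.0),
    PatientRecord("P005", 41.0, 3, 12.0, 9.0),
    PatientRecord("P006", 47.0, 3, 12.0, 3.0, dlt=1, t_dlt=2.0),
]

post = posterior_by_quadrature(patients, grid, design.ttl)
state = TrialState(now=50.0)
for p in patients:
    state.add_record(p)

print("schedule  skeleton  p_hat   P(rate > TTL)")
for s in range(grid.n_schedules):
    print(f"{grid.labels[s]:>8}  {grid.skeleton[s]:8.2f}  {post.p_hat[s]:.3f}  {post.exceed[s]:13.3f}")
print(f"\nrecommended next schedule: {select_schedule(post, state, design)}")
print(f"stopping rule status: {evaluate_stopping(post, state, design).value}")
print("\np_hat is the fitted DLT probability per schedule; the recommendation is")
print("the schedule whose fitted rate is closest to the target toxicity level")
print("(0.25), capped so escalation never skips an untried schedule.")
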