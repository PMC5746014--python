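# Methods

## Dose-toxicity model

The package implements the one-parameter empiric ("power") CRM model.
Treatment schedules are assumed monotone: toxicity (and efficacy)
increases with the schedule index, so a single curve through the
clinician-elicited skeleton `p0_1 < … < p0_K` is sufficient. The DLT
probability at schedule `s` is

    F(s, β) = p0_s ^ exp(β),        β ~ Normal(0, σ² = 1.34).

`exp(β) > 0` preserves the skeleton's ordering at every parameter value,
which is what guarantees monotone fitted rates and monotone exceedance
probabilities. The prior variance 1.34 is the conventional CRM
calibration for this model; it is configurable (`DesignConfig.prior_sd`).

Partially followed patients contribute through the TiTE-CRM weighted
Bernoulli likelihood: each record adds `(w·F)^y (1 − w·F)^{1−y}` with the
linear weight `w = follow_up / window` for a DLT-free patient and `w = 1`
for an observed DLT. The linear weight is the canonical TiTE-CRM choice;
adaptive weights are out of scope. Probabilities are clamped to
`[1e−12, 1 − 1e−12]` before logs.

## Posterior computation

Two backends share one contract (`p_hat_s = E[F(s,β) | data]`,
`exceed_s = P(F(s,β) > TTL | data)`):

* **Quadrature** (default, used inside all simulations): trapezoid rule
  on `β ∈ [−10, 10]`, starting at 2,001 nodes and doubling until
  successive passes move every `p_hat` by less than 1e−8 (converges at
  the first doubling in practice because the integrand and all its
  derivatives vanish at the boundary — prior mass outside the range is
  below 1e−16). Exceedance probabilities use the interpolated posterior
  CDF at the closed-form threshold `b_s = log(log TTL / log p0_s)`
  (F is decreasing in β, so exceedance is a lower-tail event).
  Deterministic and bit-reproducible.
* **MCMC** (cross-check): emcee ensemble sampler, 10 walkers, with
  `iterations` total retained draws after discarding `burn_in` total
  draws; defaults 10,000 and 1,000. Monte-Carlo standard errors use the
  autocorrelation-adjusted effective sample size; the exceedance MCSE
  uses a Laplace-smoothed binomial variance so that an empirical
  exceedance of exactly 0 or 1 still reports uncertainty of order
  1/ESS. An ESS under 100 logs a non-convergence warning. Seeded runs
  are bit-identical.

The two backends are required (and tested) to agree within three
Monte-Carlo standard errors on every fixture; in the limit where every
weight is 1 the quadrature posterior matches an independently coded
binary-CRM oracle to 1e−6.

## Schedule selection

The model choice is the estimated maximum tolerated schedule
`argmin_s |p_hat_s − TTL|`, ties broken to the lower schedule — the
standard CRM estimator. We considered the harder rule "highest schedule
with `p_hat ≤ TTL`" and rejected it: because `p_hat` is the posterior
*mean* of `F`, Jensen's inequality places it slightly above the true rate
when the posterior is diffuse (about +0.007 at a rate equal to the TTL
under the default prior), so the hard cut systematically excludes a
schedule whose true rate sits exactly at the TTL and is inconsistent at
that boundary. The conservatism that rule encoded lives instead in the
explicit overdose-control gate: when enabled, assignment is capped at the
highest schedule with `exceed_s` below the gate (0.25 by convention).
Escalation is additionally capped at `highest_tried + 1` (no skipping of
untried schedules); de-escalation is never restricted. The final MTD
declared by a simulated trial is the recommendation on complete
follow-up, capped at the highest schedule actually tried — an untried
schedule is never declared the MTD.

## Stopping rules

Precedence safety > success > maximum sample size; a stop, once set, is
sticky.

* **Safety**: `P(F(1,β) > TTL | data)` above the threshold (default
  0.95) — the lowest schedule is overly toxic; the trial stops and no
  schedule is declared safe. Evaluated before every enrolment decision
  and again at the final analysis. The rule watches only the lowest
  schedule; higher schedules are protected by de-escalation and the
  overdose gate.
* **Success** ("stabilisation of the MTD estimate"): `success_m` patients
  have already been assigned to the currently recommended schedule.
  `success_m = None` disables early stopping.
* **Maximum sample size**: a hard cap `max_n`.

## Enrolment gating

* **Run-in**: the first `run_in_n` (default 3) patients receive the
  lowest schedule. Two policies: `sequential-full-observation` (default,
  most conservative — each run-in patient is observed for the entire DLT
  window before the next may enrol) and `concurrent-then-wait` (run-in
  patients enrol freely; model-based allocation still waits until all are
  fully observed). The wording of run-in rules in practice supports both
  readings, hence the switch.
* **Recruitment slots**: after the run-in, one slot exists by default and
  two when more than `slot_gap` (default 4) weeks have passed since the
  previous treatment start. A started patient occupies a slot for
  `slot_gap` weeks; open slots are the base count minus occupied,
  floored at zero. Arrivals that find no open slot queue until one
  opens.
* **Assignment delay**: for a stage in which every patient receives the
  same backbone treatment initially, schedule assignment happens
  `assignment_delay` weeks (6 for such a stage, 0 otherwise) after
  enrolment, FIFO, using the posterior at the decision time; the
  patient's DLT window runs from treatment start, so backbone weeks
  count toward follow-up.

## Trial simulator

Event-driven, fully reproducible from its seed. Arrivals come from a
Poisson process (exponential inter-arrivals at `accrual_rate` patients
per week; a deterministic fixed-interval mode exists for debugging).
Each patient's latent outcome is drawn at assignment: DLT with the
scenario's true per-schedule probability, and, if toxic, a time-to-DLT
that is uniform on `[0, T]` or triangular with mode `T/2`. The outcome
is revealed only as calendar follow-up accrues (a DLT scheduled beyond
current follow-up is, for now, a censored non-event with the linear
weight — the standard TiTE information reveal). The posterior is
refreshed at every decision; the quadrature backend is used inside
simulation because it is fast and deterministic, with MCMC reserved for
cross-checks. One uniform and one timing draw are consumed per patient
unconditionally, keeping random streams aligned across scenarios that
share a seed (common random numbers for paired design comparisons);
replicate `i` of an operating-characteristics study uses seed
`master_seed + i` in every cell.

Trial duration is the calendar time from study start to the last
patient's end of follow-up (or to the decision at which a safety stop
fired). Duration therefore always reaches at least the last enrolment
time.

## 3+3 comparator

The rule-exact 3+3: cohorts of three from the lowest dose; zero DLTs
escalate, exactly one expands to six at the same dose, and at least two
DLTs among those treated at a dose (2 of 3, or 2+ of 6 — the 33%
threshold) stop escalation and declare the MTD one level below. Two or
three DLTs in a first cohort declare immediately, without expansion. If
the top dose passes, it is declared the recommended dose (a convention;
the classical description leaves the top-dose case open). Because
escalation is strictly sequential the exact selection distribution,
expected sample size and expected allocation are enumerable by binomial
arithmetic; the enumeration (capped at 8 doses) validates the
Monte-Carlo simulator within three binomial standard errors.

## Synthetic fixtures and scenarios

No real data exist for a trial being designed, so fixtures are explicit
package choices, fully configurable, and are stand-ins rather than
reproductions of any particular trial's (unpublished) numbers:

* stage presets: a six-schedule stage (skeleton 0.05, 0.10, 0.15, 0.25,
  0.35, 0.45; TTL 0.25; `max_n` 25 — the largest of the 15/20/25 grid a
  simulation study of such a stage would explore, chosen as the most
  informative single default), a four-schedule stage (`max_n` 20), and a
  six-schedule stage with the 6-week assignment delay;
* DLT window 12 weeks, accrual 1/4 patients/week, uniform DLT times by
  default — realistic for (chemo)radiotherapy toxicity follow-up;
* scenario sets built by monotone transforms of the skeleton:
  skeleton-true, shifted up (`1 − (1−p)^1.8`), shifted down (`p^1.8`),
  and steepened around the TTL (power 2.5 on both sides of the crossing)
  — realistic and extreme curves that preserve strict monotonicity.

What passing tests on these fixtures show is that the machinery is
correct and the design behaves as intended *under its own assumptions*
(monotone truth, independent patients, no dropout, accurate DLT
reporting). They do not show robustness to skeleton misspecification
beyond the shifted/steep scenarios, non-monotone truths, patient
dropout, or data-entry latency — all absent from the generator by
design.

## Problem sizes and tolerances

Default replicate count for operating-characteristics studies is 1,000;
the test suite and acceptance script use 200–500 replicates per cell and
100,000 replicates for the 3+3 validation — sizes chosen so the whole
battery runs on a single CPU in minutes while leaving Monte-Carlo error
well inside the asserted three-standard-error bands. Exact checks
(likelihood arithmetic, enumeration partition) assert at 1e−12;
quadrature-vs-oracle checks at 1e−6; stochastic checks at three
Monte-Carlo standard errors (with a 1e−6 absolute floor guarding
degenerate draws).

## Known limitations

* One-parameter model only; no two-parameter, ordinal-toxicity, efficacy
  or combination modelling.
* Stages are simulated independently; no information borrowing between
  stages and no resource contention across parallel stages.
* No patient dropout, dose modification, or multi-site accrual
  heterogeneity.
* The committee-override path that a real trial would have (a human
  group can reject the model's recommendation) is out of scope: in
  simulation the engine's recommendation is final, and a safety stop
  terminates the replicate rather than restarting at a lower drug dose.
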