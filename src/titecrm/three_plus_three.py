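"""Rule-exact 3+3 design: cohort decisions, trial simulation and exact enumeration.

The 3+3 escalates in cohorts of three starting from the lowest dose.  A
toxicity-free cohort escalates; exactly one DLT among three expands the
cohort to six at the same dose; at least two DLTs among the patients
treated at a dose (out of three or six) stop escalation, and the dose
just below is declared the MTD.  A dose at which 2/6 patients (33%) have
a DLT is therefore the first dose deemed too toxic.

Because the path space of the design is tiny, the exact distribution of
the selected dose, the expected sample size and the expected allocation
can be enumerated by summing binomial path probabilities; the Monte-Carlo
simulator is validated against that enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy.stats import binom

from .errors import ValidationError

#: Fraction of a fully expanded cohort (2 of 6) at which escalation stops.
STOP_FRACTION = 2.0 / 6.0

_MAX_ENUM_DOSES = 8


class Decision(str, Enum):
    ESCALATE = "escalate"
    EXPAND = "expand"
    DECLARE_MTD_BELOW = "declare_mtd_below"
    DECLARE_MTD_CURRENT_TOP = "declare_mtd_current_top"


@dataclass(frozen=True)
class CohortOutcome:
    """DLT count among the patients treated so far at one dose (3 or 6)."""

    dose: int
    n_treated: int
    n_dlt: int

    def __post_init__(self) -> None:
        if self.n_treated not in (3, 6):
            raise ValidationError("a 3+3 cohort has 3 or 6 patients")
        if not (0 <= self.n_dlt <= self.n_treated):
            raise ValidationError("n_dlt must lie in [0, n_treated]")


@dataclass(frozen=True)
class ThreePlusThreeResult:
    """Outcome of one simulated 3+3 trial.

    ``selected`` is the recommended dose (1-based); 0 means no dose was
    found safe (the lowest dose was already too toxic).
    """

    selected: int
    n: int
    alloc: tuple[int, ...]
    dlts: tuple[int, ...]
    seed: Optional[int] = None


def three_plus_three_decision(outcome: CohortOutcome, top_dose: int) -> Decision:
    """Apply the 3+3 escalation rule to the outcome at the current dose.

    With three treated: zero DLTs escalate (declare the top dose when
    already there), one DLT expands to six, two or more immediately stop
    with the MTD one level below.  With six treated: at most one DLT in
    total escalates (or declares the top dose), two or more stop.
    """
    at_top = outcome.dose >= top_dose
    if outcome.n_treated == 3:
        if outcome.n_dlt == 0:
            return Decision.DECLARE_MTD_CURRENT_TOP if at_top else Decision.ESCALATE
        if outcome.n_dlt == 1:
            return Decision.EXPAND
        return Decision.DECLARE_MTD_BELOW
    if outcome.n_dlt <= 1:
        return Decision.DECLARE_MTD_CURRENT_TOP if at_top else Decision.ESCALATE
    return Decision.DECLARE_MTD_BELOW


def simulate_3p3_trial(
    true_p: Sequence[float],
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> ThreePlusThreeResult:
    """Simulate one 3+3 trial under the given true per-dose DLT probabilities."""
    p = [float(x) for x in true_p]
    if not p:
        raise ValidationError("true_p must be non-empty")
    if any(not (0.0 <= x <= 1.0) for x in p):
        raise ValidationError("true_p values must lie in [0,1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    top = len(p)
    alloc = [0] * top
    dlts = [0] * top
    dose = 1
    while True:
        k1 = int(rng.binomial(3, p[dose - 1]))
        alloc[dose - 1] += 3
        dlts[dose - 1] += k1
        decision = three_plus_three_decision(CohortOutcome(dose, 3, k1), top)
        if decision is Decision.EXPAND:
            k2 = int(rng.binomial(3, p[dose - 1]))
            alloc[dose - 1] += 3
            dlts[dose - 1] += k2
            decision = three_plus_three_decision(CohortOutcome(dose, 6, k1 + k2), top)
        if decision is Decision.ESCALATE:
            dose += 1
            continue
        selected = dose if decision is Decision.DECLARE_MTD_CURRENT_TOP else dose - 1
        return ThreePlusThreeResult(
            selected=selected, n=sum(alloc), alloc=tuple(alloc), dlts=tuple(dlts), seed=seed
        )


@dataclass(frozen=True)
class ThreePlusThreeDistribution:
    """Exact selection distribution of the 3+3 under given true DLT probabilities.

    ``selection_probs[d]`` is the probability of recommending dose ``d``
    (index 0 is the "no safe dose" outcome); probabilities sum to 1.
    """

    selection_probs: tuple[float, ...]
    expected_n: float
    expected_alloc: tuple[float, ...]


def enumerate_3p3_distribution(true_p: Sequence[float]) -> ThreePlusThreeDistribution:
    """Exhaustively enumerate the 3+3 path space by binomial arithmetic.

    Escalation is strictly sequential, so the reach probability flows dose
    by dose: at a dose with DLT probability ``p`` the pass probability is
    ``P(0 of 3) + P(1 of 3) * P(0 of the next 3)`` and the complement
    declares the MTD one level below.
    """
    p = [float(x) for x in true_p]
    if not p:
        raise ValidationError("true_p must be non-empty")
    if len(p) > _MAX_ENUM_DOSES:
        raise ValidationError(
            f"exact enumeration supports at most {_MAX_ENUM_DOSES} doses, got {len(p)}"
        )
    top = len(p)
    sel = np.zeros(top + 1)
    expected_alloc = np.zeros(top)
    reach = 1.0
    for d in range(1, top + 1):
        pd = p[d - 1]
        p0 = float(binom.pmf(0, 3, pd))
        p1 = float(binom.pmf(1, 3, pd))
        pass_prob = p0 + p1 * float(binom.pmf(0, 3, pd))
        expected_alloc[d - 1] += reach * (3.0 + 3.0 * p1)
        if d == top:
            sel[top] += reach * pass_prob
        stop_prob = 1.0 - pass_prob
        sel[d - 1] += reach * stop_prob
        reach *= pass_prob
        if d == top:
            break
    return ThreePlusThreeDistribution(
        selection_probs=tuple(sel),
        expected_n=float(expected_alloc.sum()),
        expected_alloc=tuple(expected_alloc),
    )
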