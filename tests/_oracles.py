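"""Independent oracles used by the test suite.

Everything here is deliberately coded along a different route from the
package: adaptive scipy quadrature instead of fixed-grid trapezoid,
per-record product likelihoods instead of vectorised log sums, and direct
binomial arithmetic for the 3+3.  These functions validate the package;
they never stand in for it.
"""

from __future__ import annotations

import math
from typing import Sequence

from scipy.integrate import quad
from scipy.stats import norm


def product_likelihood(b: float, data: Sequence[tuple[int, int, float]],
                       skeleton: Sequence[float]) -> float:
    """Weighted Bernoulli likelihood as a plain per-record product.

    ``data`` is a list of (schedule 1-based, dlt, weight) triples.
    """
    like = 1.0
    for sched, y, w in data:
        f = skeleton[sched - 1] ** math.exp(b)
        q = w * f
        like *= q if y else (1.0 - q)
    return like


def per_record_loglik(data: Sequence[tuple[int, int, float]],
                      skeleton: Sequence[float], b: float) -> float:
    """Sum of per-record log terms evaluated one at a time."""
    total = 0.0
    for rec in data:
        total += math.log(product_likelihood(b, [rec], skeleton))
    return total


def crm_posterior_oracle(
    data: Sequence[tuple[int, int, float]],
    skeleton: Sequence[float],
    ttl: float,
    prior_sd: float,
    lim: float = 15.0,
) -> tuple[list[float], list[float], float]:
    """Fine adaptive-quadrature posterior of the one-parameter power model.

    Returns (p_hat per schedule, exceedance per schedule, posterior mean
    of the parameter).  With empty ``data`` these are the prior-implied
    summaries (prior-predictive mean of p0^exp(beta), prior exceedance).
    """

    def post_unnorm(b: float) -> float:
        return product_likelihood(b, data, skeleton) * norm.pdf(b, 0.0, prior_sd)

    z, _ = quad(post_unnorm, -lim, lim, limit=400)
    p_hat, exceed = [], []
    for s in range(1, len(skeleton) + 1):
        num, _ = quad(
            lambda b: skeleton[s - 1] ** math.exp(b) * post_unnorm(b),
            -lim, lim, limit=400,
        )
        p_hat.append(num / z)
        # F_s(beta) > ttl iff beta below the schedule-specific threshold
        b_s = math.log(math.log(ttl) / math.log(skeleton[s - 1]))
        num2, _ = quad(post_unnorm, -lim, b_s, limit=400)
        exceed.append(num2 / z)
    mean_num, _ = quad(lambda b: b * post_unnorm(b), -lim, lim, limit=400)
    return p_hat, exceed, mean_num / z
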