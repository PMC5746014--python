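"""Dose-toxicity model: weights, likelihood, quadrature and MCMC posteriors."""

import inspect
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from titecrm import (
    PatientRecord,
    ScheduleGrid,
    ValidationError,
    compute_weight,
    posterior_by_mcmc,
    posterior_by_quadrature,
    weighted_log_likelihood,
)
from titecrm.model import DEFAULT_PRIOR_SD

from _oracles import crm_posterior_oracle, per_record_loglik
from conftest import SKELETON_6, TTL, WINDOW, make_record


class TestScheduleGrid:
    def test_valid_grid(self, grid6):
        assert grid6.n_schedules == 6
        assert grid6.labels == ("S1", "S2", "S3", "S4", "S5", "S6")

    @pytest.mark.parametrize(
        "skeleton",
        [
            (0.3, 0.2),            # decreasing
            (0.1, 0.1, 0.2),       # not strictly increasing
            (0.0, 0.5),            # boundary value
            (0.5, 1.0),            # boundary value
            (0.25,),               # too few schedules
        ],
    )
    def test_invalid_skeletons_rejected(self, skeleton):
        with pytest.raises(ValidationError):
            ScheduleGrid(skeleton=skeleton)


class TestPatientRecord:
    def test_dlt_requires_timing(self):
        with pytest.raises(ValidationError):
            make_record(1, 1, 6.0, dlt=1, t_dlt=None)

    def test_t_dlt_must_precede_follow_up(self):
        with pytest.raises(ValidationError):
            make_record(1, 1, 6.0, dlt=1, t_dlt=8.0)

    def test_follow_up_bounded_by_window(self):
        with pytest.raises(ValidationError):
            make_record(1, 1, 13.0)


class TestComputeWeight:
    @pytest.mark.parametrize(
        "follow_up, window, dlt, expected",
        [
            (12.0, 12.0, 0, 1.0),   # full follow-up
            (6.0, 12.0, 0, 0.5),    # linear weight at half window
            (2.0, 12.0, 1, 1.0),    # observed DLT carries full weight
            (0.0, 12.0, 0, 0.0),
        ],
    )
    def test_examples(self, follow_up, window, dlt, expected):
        assert compute_weight(follow_up, window, dlt) == pytest.approx(expected)

    @pytest.mark.parametrize("fu, win", [(-1.0, 12.0), (13.0, 12.0), (1.0, 0.0)])
    def test_invalid_inputs(self, fu, win):
        with pytest.raises(ValidationError):
            compute_weight(fu, win, 0)

    @given(st.floats(min_value=0.0, max_value=12.0), st.floats(min_value=0.0, max_value=12.0))
    @settings(derandomize=True, max_examples=50)
    def test_monotone_in_follow_up(self, fu1, fu2):
        lo, hi = sorted([fu1, fu2])
        assert compute_weight(lo, 12.0, 0) <= compute_weight(hi, 12.0, 0)


class TestWeightedLogLikelihood:
    def test_dlt_at_param_zero_recovers_skeleton(self, grid6):
        # param = 0 makes F equal the skeleton, so one full-weight DLT at
        # the schedule with skeleton 0.25 contributes ln(0.25)
        rec = make_record(1, 4, WINDOW, dlt=1, t_dlt=3.0)
        assert weighted_log_likelihood(0.0, [rec], grid6) == pytest.approx(
            math.log(0.25), abs=1e-12
        )

    def test_half_weight_survivor(self, grid6):
        rec = make_record(1, 4, 6.0)  # weight 0.5 at skeleton 0.25
        assert weighted_log_likelihood(0.0, [rec], grid6) == pytest.approx(
            math.log(1 - 0.125), abs=1e-12
        )

    def test_empty_records_give_zero(self, grid6):
        assert weighted_log_likelihood(0.7, [], grid6) == 0.0

    def test_matches_per_record_oracle(self, grid6, partial_records_10):
        data = [(r.schedule, r.dlt, r.weight) for r in partial_records_10]
        for beta in (-1.2, 0.0, 0.37, 2.0):
            assert weighted_log_likelihood(beta, partial_records_10, grid6) == pytest.approx(
                per_record_loglik(data, SKELETON_6, beta), abs=1e-12
            )

    def test_additive_over_concatenation(self, grid6, partial_records_10):
        a, b = partial_records_10[:4], partial_records_10[4:]
        whole = weighted_log_likelihood(0.5, partial_records_10, grid6)
        parts = weighted_log_likelihood(0.5, a, grid6) + weighted_log_likelihood(0.5, b, grid6)
        assert whole == pytest.approx(parts, abs=1e-12)

    def test_unknown_schedule_rejected(self, grid6):
        rec = make_record(1, 9, 6.0)
        with pytest.raises(ValidationError):
            weighted_log_likelihood(0.0, [rec], grid6)


class TestQuadraturePosterior:
    def test_prior_predictive_matches_fine_integration(self, grid6):
        # frozen from the adaptive-quadrature oracle over the Normal(0, 1.34) prior
        expected = (0.15906599, 0.20496399, 0.24283027, 0.31040203, 0.37511597, 0.44126798)
        post = posterior_by_quadrature([], grid6, TTL)
        np.testing.assert_allclose(post.p_hat, expected, atol=1e-6)
        oracle_p, oracle_e, _ = crm_posterior_oracle([], SKELETON_6, TTL, DEFAULT_PRIOR_SD)
        np.testing.assert_allclose(post.p_hat, oracle_p, atol=1e-6)
        np.testing.assert_allclose(post.exceed, oracle_e, atol=1e-4)

    def test_binary_crm_limit(self, grid6, full_records_10):
        # all weights are 1, so the TiTE posterior must equal a plain
        # binary-CRM posterior computed by an independent oracle
        data = [(r.schedule, r.dlt, 1.0) for r in full_records_10]
        oracle_p, _, oracle_mean = crm_posterior_oracle(data, SKELETON_6, TTL, DEFAULT_PRIOR_SD)
        post = posterior_by_quadrature(full_records_10, grid6, TTL)
        np.testing.assert_allclose(post.p_hat, oracle_p, atol=1e-6)
        assert post.param_mean == pytest.approx(oracle_mean, abs=1e-6)

    def test_partial_weights_match_oracle(self, grid6, partial_records_10):
        data = [(r.schedule, r.dlt, r.weight) for r in partial_records_10]
        oracle_p, oracle_e, _ = crm_posterior_oracle(data, SKELETON_6, TTL, DEFAULT_PRIOR_SD)
        post = posterior_by_quadrature(partial_records_10, grid6, TTL)
        np.testing.assert_allclose(post.p_hat, oracle_p, atol=1e-6)
        np.testing.assert_allclose(post.exceed, oracle_e, atol=1e-4)

    def test_monotone_summaries(self, grid6, partial_records_10):
        post = posterior_by_quadrature(partial_records_10, grid6, TTL)
        assert np.all(np.diff(post.p_hat) > 0)
        assert np.all(np.diff(post.exceed) >= 0)

    def test_data_dominance(self, grid6, partial_records_10):
        # appending a fully observed DLT never decreases any fitted rate
        base = posterior_by_quadrature(partial_records_10, grid6, TTL)
        for s in (1, 4, 6):
            extra = make_record(99, s, WINDOW, dlt=1, t_dlt=5.0)
            bumped = posterior_by_quadrature(partial_records_10 + [extra], grid6, TTL)
            assert np.all(bumped.p_hat >= base.p_hat - 1e-12)

    def test_invalid_ttl(self, grid6):
        with pytest.raises(ValidationError):
            posterior_by_quadrature([], grid6, 1.5)


class TestMCMCPosterior:
    def test_paper_defaults(self):
        sig = inspect.signature(posterior_by_mcmc)
        assert sig.parameters["iterations"].default == 10_000
        assert sig.parameters["burn_in"].default == 1_000

    def test_agrees_with_quadrature_within_mc_error(self, grid6, partial_records_10):
        quad = posterior_by_quadrature(partial_records_10, grid6, TTL)
        mcmc = posterior_by_mcmc(partial_records_10, grid6, TTL, seed=7)
        assert np.all(np.abs(mcmc.p_hat - quad.p_hat) <= 3 * mcmc.mcse_p_hat + 1e-6)

    def test_seeded_reproducibility(self, grid6, partial_records_10):
        a = posterior_by_mcmc(partial_records_10, grid6, TTL, iterations=2000,
                              burn_in=200, seed=42)
        b = posterior_by_mcmc(partial_records_10, grid6, TTL, iterations=2000,
                              burn_in=200, seed=42)
        assert np.array_equal(a.p_hat, b.p_hat)
        assert np.array_equal(a.exceed, b.exceed)
        assert a.param_mean == b.param_mean

    def test_iteration_validation(self, grid6):
        with pytest.raises(ValidationError):
            posterior_by_mcmc([], grid6, TTL, iterations=100, burn_in=200)
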