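import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breechscan import (
    CohortSummary,
    MCMCConfig,
    RRPrior,
    elicit_normal_prior,
    fit_logbinomial,
    grid_posterior_oracle,
    number_needed_to_scan,
    posterior_prob_reduction,
    sensitivity_flat,
    weakly_informative_prior,
    zero_event_correction,
)


def summary(a, n1, c, n2, name="outcome"):
    return CohortSummary(name, ("before", "after"), (a, c), (n1, n2))


class TestPriorElicitation:
    def test_symmetric_interval_forces_zero_mean(self):
        prior = elicit_normal_prior(1.0, 0.5, 2.0)
        assert prior.mu == pytest.approx(0.0)
        assert prior.sigma == pytest.approx(math.log(4) / (2 * 1.959964))

    def test_same_log_width_same_sigma(self):
        p1 = elicit_normal_prior(1.0, 0.5, 2.0)
        p2 = elicit_normal_prior(0.5, 0.25, 1.0)
        assert p2.mu == pytest.approx(math.log(0.5))
        assert p2.sigma == pytest.approx(p1.sigma)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.floats(0.05, 5.0),
        st.floats(1.05, 4.0),
    )
    def test_round_trip_recovers_interval(self, rr, spread):
        lo, hi = rr / spread, rr * spread
        prior = elicit_normal_prior(rr, lo, hi)
        assert math.exp(prior.mu - 1.959964 * prior.sigma) == pytest.approx(lo)
        assert math.exp(prior.mu + 1.959964 * prior.sigma) == pytest.approx(hi)

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            elicit_normal_prior(0.5, 0.8, 1.0)


class TestZeroEventCorrection:
    def test_zero_cell_gains_single_event(self):
        corrected = zero_event_correction(summary(0, 167, 3, 142))
        assert corrected.events == (1, 3)
        assert corrected.totals == (167, 142)
        assert corrected.zero_corrected

    def test_no_zero_cell_untouched(self):
        s = summary(5, 100, 7, 100)
        assert zero_event_correction(s) is s

    def test_double_zero_corrects_both(self):
        corrected = zero_event_correction(summary(0, 50, 0, 60))
        assert corrected.events == (1, 1)


class TestSampler:
    def test_determinism_under_fixed_seed(self):
        s = summary(27, 167, 5, 142)
        mcmc = MCMCConfig(seed=3)
        f1 = fit_logbinomial(s, weakly_informative_prior(), mcmc)
        f2 = fit_logbinomial(s, weakly_informative_prior(), mcmc)
        assert f1.rr_median == f2.rr_median
        assert np.array_equal(f1.samples, f2.samples)

    def test_degenerate_prior_pins_rr_at_prior_mean(self):
        s = summary(27, 167, 5, 142)
        prior = RRPrior(mu=0.0, sigma=1e-6)
        fit = fit_logbinomial(s, prior, MCMCConfig(seed=0))
        assert fit.rr_median == pytest.approx(1.0, abs=1e-3)

    def test_consistency_crude_rr_recovered_at_large_n(self):
        # totals x100 with fixed risks: posterior median approaches crude RR
        s = summary(1000, 10_000, 500, 10_000)
        fit = sensitivity_flat(s, MCMCConfig(n_iter=4000, seed=2))
        assert fit.rr_median == pytest.approx(0.5, rel=0.02)

    def test_rhat_near_one_on_well_mixed_fit(self):
        fit = sensitivity_flat(summary(20, 100, 10, 100), MCMCConfig(seed=1))
        assert fit.rhat < 1.05
        assert 0.1 <= fit.accept_rate <= 0.6
        assert fit.warnings == ()

    def test_shrinkage_direction_follows_prior(self):
        """Informative prior pulls the posterior median toward the prior
        mean relative to the flat fit, in the sign of (mu - crude log RR)."""
        rng = np.random.default_rng(8)
        for _ in range(5):
            n1, n2 = 150, 150
            a = int(rng.integers(8, 40))
            c = int(rng.integers(8, 40))
            s = summary(a, n1, c, n2)
            crude = math.log((c / n2) / (a / n1))
            prior = RRPrior(mu=crude + float(rng.choice([-1.0, 1.0])), sigma=0.3)
            flat = sensitivity_flat(s, MCMCConfig(seed=0, n_iter=3000))
            info = fit_logbinomial(s, prior, MCMCConfig(seed=0, n_iter=3000))
            shift = math.log(info.rr_median) - math.log(flat.rr_median)
            assert math.copysign(1, shift) == math.copysign(1, prior.mu - crude)


class TestGridOracle:
    def test_symmetric_counts_centre_at_unity(self):
        oracle = grid_posterior_oracle(
            summary(10, 100, 10, 100), weakly_informative_prior()
        )
        assert oracle.rr_median == pytest.approx(1.0, abs=0.03)
        assert oracle.prob_reduction == pytest.approx(0.5, abs=0.02)

    def test_likelihood_dominance_at_large_counts(self):
        oracle = grid_posterior_oracle(
            summary(1000, 10_000, 500, 10_000), weakly_informative_prior()
        )
        assert oracle.rr_median == pytest.approx(0.5, rel=0.01)

    def test_prob_reduction_monotone_decreasing_in_prior_mu(self):
        s = summary(15, 120, 9, 110)
        probs = [
            grid_posterior_oracle(s, RRPrior(mu=mu, sigma=0.5)).prob_reduction
            for mu in (-1.0, -0.5, 0.0, 0.5, 1.0)
        ]
        assert all(p1 > p2 for p1, p2 in zip(probs, probs[1:]))


class TestProbReduction:
    def test_symmetric_draws_give_half(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(0.0, 1.0, 20_000)
        draws = np.concatenate([draws, -draws])  # exactly symmetric
        assert posterior_prob_reduction(draws) == pytest.approx(0.5, abs=1e-12)

    def test_agrees_with_empirical_tail_fraction(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n1, n2 = int(rng.integers(80, 300)), int(rng.integers(80, 300))
            a = int(rng.integers(5, n1 // 3))
            c = int(rng.integers(5, n2 // 3))
            fit = sensitivity_flat(
                summary(a, n1, c, n2), MCMCConfig(seed=int(rng.integers(2**31)))
            )
            empirical = float((fit.beta_draws < 0).mean())
            assert fit.prob_reduction == pytest.approx(empirical, abs=0.02)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            posterior_prob_reduction(np.zeros(50))


class TestSensitivityFlat:
    def test_flat_and_informative_converge_at_large_n(self):
        s = summary(1400, 10_000, 700, 10_000)
        prior = elicit_normal_prior(1.0, 0.5, 2.0)
        flat = sensitivity_flat(s, MCMCConfig(seed=5, n_iter=4000))
        info = fit_logbinomial(s, prior, MCMCConfig(seed=5, n_iter=4000))
        assert flat.rr_median == pytest.approx(info.rr_median, rel=0.03)

    def test_improper_flat_close_to_weak_default(self):
        s = summary(27, 167, 5, 142)
        weak = grid_posterior_oracle(s, weakly_informative_prior())
        improper = grid_posterior_oracle(
            s, RRPrior(mu=0.0, sigma=10.0, flavour="improper_flat")
        )
        assert weak.rr_median == pytest.approx(improper.rr_median, rel=0.02)


class TestNumberNeededToScan:
    def test_study_scale_point_estimate(self):
        nns, (lo, hi) = number_needed_to_scan(summary(82, 16_777, 7, 7_351))
        assert nns == 255
        assert lo == 192
        assert hi in (375, 376)

    def test_wald_interval_matches_independent_arithmetic(self):
        a, n1, c, n2 = 82, 16_777, 7, 7_351
        p1, p2 = a / n1, c / n2
        se = math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
        assert se == pytest.approx(6.476e-4, rel=1e-3)
        rd = p1 - p2
        nns, (lo, hi) = number_needed_to_scan(summary(a, n1, c, n2), rounding="outward")
        assert lo == math.floor(1 / (rd + 1.959964 * se))
        assert hi == math.ceil(1 / (rd - 1.959964 * se))

    def test_equal_risks_undefined(self):
        with pytest.raises(ValueError, match="NNS undefined"):
            number_needed_to_scan(summary(5, 100, 5, 100))

    def test_negative_lower_bound_gives_infinite_upper(self):
        nns, (lo, hi) = number_needed_to_scan(summary(4, 100, 2, 100))
        assert hi == math.inf
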