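"""Monte-Carlo studies: correlation replications and case-control splits."""

import numpy as np
import pytest
from scipy import stats

from noisychain import (
    RAW_WEIGHTS,
    STANDARDIZED_INPUT,
    ChainSpec,
    ChainValidationError,
    EmptyGroupError,
    MonteCarloDesign,
    analytic_correlation,
    analytic_group_d,
    classify_groups,
    cohens_d_vs_population,
    run_correlation_study,
    run_group_study,
)


class TestClassifyGroups:
    def test_boundary_belongs_to_controls(self):
        mask = classify_groups(np.array([-2.5, -2.0, 0.3]), cutoff=-2.0)
        assert mask.tolist() == [True, False, False]

    def test_all_above_cutoff_gives_empty_case_group(self):
        assert not classify_groups(np.array([0.1, 1.0]), cutoff=-2.0).any()

    def test_tail_fraction_matches_normal_cdf(self, rng):
        scores = rng.standard_normal(10_000)
        count = classify_groups(scores, -2.0).sum()
        expected = 10_000 * stats.norm.cdf(-2)
        assert abs(count - expected) < 3 * np.sqrt(expected)


class TestCohensD:
    def test_hand_computed_example(self):
        # means -2 and 1, full-sample sd([-2, 0, 2], ddof=1) = 2
        d = cohens_d_vs_population(np.array([-2.0, 0.0, 2.0]), np.array([True, False, False]))
        assert d == pytest.approx(-1.5, abs=1e-12)

    def test_identical_group_means_give_zero(self):
        d = cohens_d_vs_population(np.array([0.0, 3.0, 3.0, 0.0]),
                                   np.array([True, False, True, False]))
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(EmptyGroupError):
            cohens_d_vs_population(np.array([1.0, 2.0]), np.array([False, False]))

    def test_converges_to_truncated_normal_prediction(self, rng):
        """Direct bivariate-normal draws: the case-control difference on the
        predictor approaches rho times the truncated-mean gap."""
        n, rho = 2_000_000, 0.5
        z = rng.standard_normal((2, n))
        predictor = z[0]
        outcome = rho * z[0] + np.sqrt(1 - rho**2) * z[1]
        d = cohens_d_vs_population(predictor, classify_groups(outcome, -2.0))
        assert d == pytest.approx(analytic_group_d(rho, -2.0), abs=0.02)


class TestCorrelationStudy:
    def test_point_estimate_matches_oracle(self):
        spec = ChainSpec.constant(0.5, 1, RAW_WEIGHTS)
        design = MonteCarloDesign(1_000, 400, rng_seed=7)
        summary = run_correlation_study(spec, design)
        rho = analytic_correlation(0.5, 1, RAW_WEIGHTS)
        assert summary.point_estimate == pytest.approx(rho, abs=3 * summary.mc_standard_error)
        assert summary.ci_lower <= summary.point_estimate <= summary.ci_upper
        assert np.all(np.abs(summary.replication_estimates) <= 1)

    def test_noiseless_chain_degenerate_interval(self):
        summary = run_correlation_study(
            ChainSpec.constant(1.0, 0), MonteCarloDesign(100, 20, rng_seed=1)
        )
        assert summary.point_estimate == pytest.approx(1.0, abs=1e-12)
        assert summary.ci_lower == pytest.approx(1.0, abs=1e-12)
        assert summary.ci_upper == pytest.approx(1.0, abs=1e-12)

    def test_ci_width_tracks_fisher_approximation(self):
        """The empirical 95% band should be close to the Fisher large-sample
        width 2 * 1.96 * (1 - rho^2) / sqrt(n - 1)."""
        spec = ChainSpec.constant(0.5, 1, RAW_WEIGHTS)
        design = MonteCarloDesign(1_000, 500, rng_seed=11)
        summary = run_correlation_study(spec, design)
        rho = analytic_correlation(0.5, 1, RAW_WEIGHTS)
        expected_width = 2 * 1.96 * (1 - rho**2) / np.sqrt(design.n_participants - 1)
        width = summary.ci_upper - summary.ci_lower
        assert width == pytest.approx(expected_width, rel=0.15)

    def test_seed_determinism(self):
        spec = ChainSpec.constant(0.5, 2, RAW_WEIGHTS)
        a = run_correlation_study(spec, MonteCarloDesign(200, 50, rng_seed=3))
        b = run_correlation_study(spec, MonteCarloDesign(200, 50, rng_seed=3))
        c = run_correlation_study(spec, MonteCarloDesign(200, 50, rng_seed=4))
        assert np.array_equal(a.replication_estimates, b.replication_estimates)
        assert a.point_estimate == b.point_estimate
        assert not np.array_equal(a.replication_estimates, c.replication_estimates)


class TestGroupStudy:
    def test_effect_matches_oracle(self):
        spec = ChainSpec.constant(0.8, 0, STANDARDIZED_INPUT)
        design = MonteCarloDesign(10_000, 100, rng_seed=5)
        summary = run_group_study(spec, design)
        expected = analytic_group_d(analytic_correlation(0.8, 0, STANDARDIZED_INPUT), -2.0)
        assert summary.d_estimate == pytest.approx(
            expected, abs=max(3 * summary.mc_standard_error, 0.01)
        )
        assert summary.n_excluded_replications == 0

    def test_case_fraction_matches_normal_tail(self):
        spec = ChainSpec.constant(0.5, 0, STANDARDIZED_INPUT)
        design = MonteCarloDesign(10_000, 100, rng_seed=9)
        summary = run_group_study(spec, design)
        frac = summary.mean_group_sizes[0] / design.n_participants
        se = np.sqrt(stats.norm.cdf(-2) * stats.norm.sf(-2) / (100 * 10_000))
        assert abs(frac - stats.norm.cdf(-2)) < 3 * se

    def test_independent_skills_give_zero_effect(self):
        spec = ChainSpec.constant(0.0, 0, STANDARDIZED_INPUT)
        summary = run_group_study(spec, MonteCarloDesign(10_000, 50, rng_seed=2))
        assert summary.d_estimate == pytest.approx(0.0, abs=5 * summary.mc_standard_error)

    def test_small_samples_warn(self):
        spec = ChainSpec.constant(0.5, 0, STANDARDIZED_INPUT)
        with pytest.warns(UserWarning, match="fewer than 1,000"):
            run_group_study(spec, MonteCarloDesign(500, 10, rng_seed=1))

    def test_empty_group_replications_are_excluded_and_counted(self):
        spec = ChainSpec.constant(0.5, 0, STANDARDIZED_INPUT)
        design = MonteCarloDesign(1_000, 40, rng_seed=13)
        summary = run_group_study(spec, design, cutoff=-4.0)
        assert summary.n_excluded_replications > 0
        assert (
            summary.replication_estimates.size + summary.n_excluded_replications
            == design.n_replications
        )

    def test_all_replications_empty_is_an_error(self):
        spec = ChainSpec.constant(0.5, 0, STANDARDIZED_INPUT)
        with pytest.raises(ChainValidationError):
            run_group_study(spec, MonteCarloDesign(1_000, 3, rng_seed=1), cutoff=-30.0)

    def test_seed_determinism(self):
        spec = ChainSpec.constant(0.5, 1, STANDARDIZED_INPUT)
        a = run_group_study(spec, MonteCarloDesign(5_000, 20, rng_seed=21))
        b = run_group_study(spec, MonteCarloDesign(5_000, 20, rng_seed=21))
        assert np.array_equal(a.replication_estimates, b.replication_estimates)
        assert a.d_estimate == b.d_estimate
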