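"""Likelihood kernel, per-site posteriors and credible machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

import varfreq as vf
from varfreq.core_bayes import log_averaged_kernel

from conftest import quadrature_posterior


class TestObservedVariantProb:
    @pytest.mark.parametrize(
        "f, e, expected",
        [(0.5, 0.2, 0.5), (0.0, 0.3, 0.3), (0.2, 0.0, 0.2), (1.0, 0.25, 0.75)],
    )
    def test_values(self, f, e, expected):
        assert vf.observed_variant_prob(f, e) == pytest.approx(expected)

    @pytest.mark.parametrize("f, e", [(-0.1, 0.2), (1.1, 0.2), (0.5, -0.01), (0.5, 2)])
    def test_rejects_out_of_range(self, f, e):
        with pytest.raises(ValueError):
            vf.observed_variant_prob(f, e)

    @settings(max_examples=100, derandomize=True)
    @given(
        f=st.floats(0, 1, allow_nan=False),
        e=st.floats(0, 1, allow_nan=False),
    )
    def test_range_and_complement_symmetry(self, f, e):
        p = vf.observed_variant_prob(f, e)
        assert 0.0 <= p <= 1.0
        # flipping the true allele flips the observation probability
        assert vf.observed_variant_prob(1.0 - f, e) == pytest.approx(1.0 - p)


class TestPhredToError:
    @pytest.mark.parametrize("q, expected", [(10, 0.1), (0, 1.0), (30, 0.001)])
    def test_values(self, q, expected):
        assert vf.phred_to_error(q) == pytest.approx(expected, rel=1e-12)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            vf.phred_to_error(-1)

    def test_monotone_decreasing(self):
        qs = np.linspace(0, 80, 30)
        es = [vf.phred_to_error(q) for q in qs]
        assert np.all(np.diff(es) < 0)


class TestAveragedKernel:
    def test_trivial_integrand_is_one(self):
        assert vf.averaged_kernel(0, 0, 0.1, 0.9) == pytest.approx(1.0)

    def test_degenerate_interval_is_pointwise(self):
        assert vf.averaged_kernel(2, 5, 0.3, 0.3) == pytest.approx(
            0.3**2 * 0.7**3, rel=1e-12
        )

    def test_matches_adaptive_quadrature(self):
        value, _ = quad(lambda x: x**3 * (1 - x) ** 7, 0.1, 0.2, epsrel=1e-12)
        assert vf.averaged_kernel(3, 10, 0.1, 0.2) == pytest.approx(
            value / 0.1, rel=1e-8
        )

    def test_rejects_n_greater_than_m(self):
        with pytest.raises(ValueError):
            vf.averaged_kernel(5, 3, 0.1, 0.2)

    @settings(max_examples=100, derandomize=True)
    @given(
        n=st.integers(0, 40),
        extra=st.integers(0, 40),
        a=st.floats(0, 1, allow_nan=False),
        b=st.floats(0, 1, allow_nan=False),
    )
    def test_symmetric_and_nonnegative(self, n, extra, a, b):
        m = n + extra
        forward = log_averaged_kernel(n, m, a, b)[0]
        backward = log_averaged_kernel(n, m, b, a)[0]
        assert forward == backward  # exact swap invariance
        assert np.exp(forward) >= 0.0

    def test_narrow_interval_fallback_is_accurate(self):
        # so narrow that the incomplete-beta difference cancels entirely
        a, b = 0.3, 0.3 + 1e-13
        assert vf.averaged_kernel(10, 30, a, b) == pytest.approx(
            0.3**10 * 0.7**20, rel=1e-6
        )


class TestSiteObservation:
    def test_rejects_n_above_m(self):
        with pytest.raises(ValueError):
            vf.SiteObservation(5, 3, 30.0)

    def test_quality_undefined_requires_no_variant_reads(self):
        with pytest.raises(ValueError):
            vf.SiteObservation(2, 10, None)
        obs = vf.SiteObservation(0, 10, None)
        # the error window falls back to the configured floor quality
        assert obs.error_bound(20.0) == pytest.approx(0.01)


class TestSitePosterior:
    def test_no_reads_returns_prior(self, uniform_prior):
        post = vf.site_posterior(uniform_prior, vf.SiteObservation(0, 0, None))
        assert np.array_equal(post.weights, uniform_prior.weights)

    def test_high_quality_mode_at_observed_frequency(self, uniform_prior):
        post = vf.site_posterior(uniform_prior, vf.SiteObservation(5, 10, 60.0))
        assert vf.map_frequency(post) == pytest.approx(0.5)

    def test_matches_quadrature_oracle(self, uniform_prior):
        obs = vf.SiteObservation(3, 10, 20.0)
        oracle = quadrature_posterior(3, 10, 20.0, uniform_prior)
        post = vf.site_posterior(uniform_prior, obs)
        assert np.max(np.abs(post.weights - oracle) / oracle) < 1e-6

    def test_normalized(self, uniform_prior):
        post = vf.site_posterior(uniform_prior, vf.SiteObservation(17, 80, 33.0))
        assert abs(post.weights.sum() - 1.0) <= 1e-9

    def test_negligible_error_matches_pure_binomial(self, uniform_prior, grid_values):
        # for Q >= 80 the error window is so small the kernel is binomial
        n, m = 13, 50
        post = vf.site_posterior(uniform_prior, vf.SiteObservation(n, m, 80.0))
        logb = n * np.log(np.where(grid_values > 0, grid_values, 1)) + (
            m - n
        ) * np.log1p(-np.where(grid_values < 1, grid_values, 0))
        logb[0] = -np.inf  # f = 0 impossible for n > 0
        logb[-1] = -np.inf
        binom = np.exp(logb - logb.max())
        binom /= binom.sum()
        assert 0.5 * np.abs(post.weights - binom).sum() < 1e-6
        assert vf.map_frequency(post) == pytest.approx(
            grid_values[np.argmin(np.abs(grid_values - n / m))]
        )


class TestHypothesisPosterior:
    def test_point_mass(self):
        post = vf.GridDistribution.point_mass(0.5)
        assert vf.hypothesis_posterior(post, vf.Hypothesis((0.5,))) == 1.0

    def test_completeness(self, uniform_prior, grid_values):
        h = vf.Hypothesis(tuple(grid_values))
        assert vf.hypothesis_posterior(uniform_prior, h) == pytest.approx(1.0)

    def test_single_atom_of_uniform(self, uniform_prior):
        assert vf.hypothesis_posterior(
            uniform_prior, vf.Hypothesis((0.0,))
        ) == pytest.approx(1 / 101)

    def test_complement_rule(self, uniform_prior, grid_values):
        h = vf.Hypothesis(tuple(grid_values[:30]))
        hc = vf.Hypothesis(tuple(grid_values[30:]))
        total = vf.hypothesis_posterior(uniform_prior, h) + vf.hypothesis_posterior(
            uniform_prior, hc
        )
        assert total == pytest.approx(1.0)

    def test_off_grid_member_rejected(self, uniform_prior):
        with pytest.raises(ValueError):
            vf.hypothesis_posterior(uniform_prior, vf.Hypothesis((0.005,)))


class TestCredibleSet:
    def test_point_mass(self):
        post = vf.GridDistribution.point_mass(0.37)
        assert vf.credible_set(post, 0.05).members == (0.37,)

    def test_uniform_needs_96_of_101(self, uniform_prior):
        assert len(vf.credible_set(uniform_prior, 0.05).members) == 96

    def test_two_atoms(self, grid_values):
        weights = np.zeros(101)
        weights[50] = 0.7
        weights[100] = 0.3
        post = vf.GridDistribution(grid_values, weights)
        assert vf.credible_set(post, 0.4).members == (0.5,)

    @settings(max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000), alpha=st.floats(0.01, 0.4))
    def test_minimality_and_coverage(self, seed, alpha):
        rng = np.random.default_rng(seed)
        weights = rng.random(101)
        post = vf.GridDistribution(np.linspace(0, 1, 101), weights / weights.sum())
        members = vf.credible_set(post, alpha).members
        idx = [np.argmin(np.abs(post.values - f)) for f in members]
        total = post.weights[idx].sum()
        assert total >= 1 - alpha - 1e-9
        smallest = post.weights[idx].min()
        assert total - smallest < 1 - alpha


class TestMaxConfidentFrequency:
    def test_point_mass(self):
        post = vf.GridDistribution.point_mass(0.37)
        assert vf.max_confident_frequency(post, 1e-6) == pytest.approx(0.37)

    def test_reference_point_mass(self):
        post = vf.GridDistribution.point_mass(0.0)
        assert vf.max_confident_frequency(post, 0.3) == 0.0

    def test_split_atoms(self, grid_values):
        weights = np.zeros(101)
        weights[0] = 0.5
        weights[100] = 0.5
        post = vf.GridDistribution(grid_values, weights)
        # tail at any f > 0 is 0.5 < 0.6
        assert vf.max_confident_frequency(post, 0.4) == 0.0

    def test_tail_mass_is_monotone_nonincreasing(self, uniform_prior, grid_values):
        tails = [vf.tail_mass(uniform_prior, f) for f in grid_values]
        assert np.all(np.diff(tails) <= 1e-15)


class TestPointSummaries:
    def test_point_mass(self):
        post = vf.GridDistribution.point_mass(0.5)
        assert vf.map_frequency(post) == 0.5
        assert vf.expected_frequency(post) == 0.5

    def test_map_tie_goes_to_lowest_frequency(self, grid_values):
        weights = np.zeros(101)
        weights[0] = 0.5
        weights[100] = 0.5
        post = vf.GridDistribution(grid_values, weights)
        assert vf.map_frequency(post) == 0.0
        assert vf.expected_frequency(post) == pytest.approx(0.5)

    def test_uniform_expectation(self, uniform_prior):
        assert vf.expected_frequency(uniform_prior) == pytest.approx(0.5)


class TestGridTypes:
    def test_grid_invariants(self):
        grid = vf.FrequencyGrid()
        values = grid.values
        assert values[0] == 0.0 and values[-1] == 1.0 and values.size == 101
        assert np.allclose(np.diff(values), 0.01)

    def test_resolution_must_divide_one(self):
        with pytest.raises(ValueError):
            vf.FrequencyGrid(0.03)

    def test_coarser_grid(self):
        assert vf.FrequencyGrid(0.02).values.size == 51

    def test_distribution_rejects_bad_weights(self, grid_values):
        with pytest.raises(ValueError):
            vf.GridDistribution(grid_values, np.full(101, 0.5))
        weights = np.zeros(101)
        weights[0] = 1.5
        weights[1] = -0.5
        with pytest.raises(ValueError):
            vf.GridDistribution(grid_values, weights)

    def test_empty_hypothesis_rejected(self):
        with pytest.raises(ValueError):
            vf.Hypothesis(())
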