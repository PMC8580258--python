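import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logsumexp

from latentcause import (
    GridSpec,
    InternalModel,
    log_L0,
    log_L1_exact,
    log_L1_quadrature,
    log_L_given_mu,
    log_L_given_z,
    log_joint_likelihood,
    log_partition_prior,
    posterior_mean_mu,
    posterior_mu_mixture,
)
from latentcause.inference import PARTITION_CAP, partition_matrix

from .conftest import random_trials
from .oracles import brute_log_joint, brute_log_L_given_mu, quad_log_L_given_z


class TestLogL0:
    def test_closed_form(self):
        assert log_L0(np.zeros((1, 2)), InternalModel(R=1.0)) == pytest.approx(
            -math.log(math.pi)
        )
        assert log_L0(np.zeros((6, 2)), InternalModel()) == pytest.approx(
            -6 * math.log(100 * math.pi)
        )

    def test_empty_stimulus(self):
        assert log_L0(np.empty((0, 2)), InternalModel()) == 0.0


class TestPartitionPrior:
    def test_symmetric_prior(self):
        z = [1, 0, 1, 1, 0, 0]
        assert log_partition_prior(z, 0.5) == pytest.approx(math.log(1 / 64))

    def test_impossible_partition_is_minus_inf(self):
        assert log_partition_prior([1, 0, 0], 0.0) == -np.inf
        assert log_partition_prior([1, 1, 0], 1.0) == -np.inf
        assert log_partition_prior([0, 0], 0.0) == 0.0

    @given(st.floats(0.01, 0.99))
    @settings(max_examples=20, deadline=None)
    def test_normalises_over_all_partitions(self, p_aff):
        Z = partition_matrix(5)
        logs = [log_partition_prior(z, p_aff) for z in Z.astype(int)]
        assert logsumexp(logs) == pytest.approx(0.0, abs=1e-12)

    def test_invalid_p_aff(self):
        with pytest.raises(ValueError):
            log_partition_prior([1, 0], 1.5)


class TestJointLikelihood:
    def test_all_background_equals_L0_for_any_mu(self, model):
        x = np.array([[1.0, 2.0], [-3.0, 0.5]])
        for mu in ([0, 0], [5, -5]):
            assert log_joint_likelihood([0, 0], mu, x, model) == pytest.approx(
                log_L0(x, model)
            )

    def test_gaussian_peak_value(self, model):
        x = np.array([[1.0, -2.0]])
        got = log_joint_likelihood([1], x[0], x, model)
        assert got == pytest.approx(math.log(1 / (2 * math.pi * 4)))

    def test_matches_per_point_oracle(self, model):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(1, 7))
            x = rng.uniform(-8, 8, (n, 2))
            z = rng.integers(0, 2, n)
            mu = rng.normal(0, 3, 2)
            assert log_joint_likelihood(z, mu, x, model) == pytest.approx(
                brute_log_joint(z, mu, x, model), rel=1e-12
            )


class TestMarginalOverMu:
    def test_null_partition_equals_L0_exactly(self, model):
        for t in random_trials(10, seed=2):
            z = np.zeros(t.N, dtype=int)
            assert log_L_given_z(z, t, model) == log_L0(t, model)

    def test_single_point_closed_form(self, model):
        # one affiliated point at the origin: the marginal is the 2-D normal
        # with variance sigma^2 + sigma_s^2 evaluated at zero
        x = np.array([[0.0, 0.0]])
        expected = math.log(1 / (2 * math.pi * 8))
        assert log_L_given_z([1], x, model) == pytest.approx(expected, rel=1e-12)

    def test_matches_adaptive_quadrature(self, model):
        rng = np.random.default_rng(3)
        for _ in range(8):
            n = int(rng.integers(1, 7))
            x = rng.uniform(-8, 8, (n, 2))
            z = rng.integers(0, 2, n)
            got = log_L_given_z(z, x, model)
            want = quad_log_L_given_z(z, x, model)
            assert got == pytest.approx(want, rel=1e-9)


class TestLikelihoodOverMu:
    def test_zero_affiliation_belief_reduces_to_background(self):
        m = InternalModel(p_aff=0.0)
        x = np.array([[1.0, 1.0], [2.0, -1.0]])
        assert log_L_given_mu([0, 0], x, m) == pytest.approx(log_L0(x, m))

    def test_single_point_arithmetic(self, model):
        x = np.array([[0.0, 0.0]])
        want = math.log(0.5 / (100 * math.pi) + 0.5 / (8 * math.pi))
        assert log_L_given_mu([0.0, 0.0], x, model) == pytest.approx(want)

    def test_mixture_form_equals_partition_sum(self, model):
        # the per-point product form and the explicit sum over 2^N partitions
        # are two factorisations of the same marginal
        rng = np.random.default_rng(4)
        for _ in range(5):
            n = int(rng.integers(2, 8))
            x = rng.uniform(-6, 6, (n, 2))
            mu = rng.normal(0, 2, 2)
            assert log_L_given_mu(mu, x, model) == pytest.approx(
                brute_log_L_given_mu(mu, x, model), rel=1e-10
            )


class TestEvidence:
    def test_single_point_closed_form(self, model):
        x = np.array([[0.0, 0.0]])
        want = math.log(0.5 / (100 * math.pi) + 0.5 / (16 * math.pi))
        assert log_L1_exact(x, model) == pytest.approx(want, rel=1e-10)

    def test_zero_affiliation_belief_equals_L0(self):
        m = InternalModel(p_aff=0.0)
        for t in random_trials(5, seed=5):
            assert log_L1_exact(t, m) == pytest.approx(log_L0(t, m), abs=1e-12)

    def test_capacity_error_beyond_cap(self, model):
        x = np.zeros((PARTITION_CAP + 1, 2))
        with pytest.raises(ValueError, match="quadrature"):
            log_L1_exact(x, model)

    def test_quadrature_grid_convergence(self, model):
        t = random_trials(1, seed=6)[0]
        a = log_L1_quadrature(t, model, GridSpec(n_nodes=201))
        b = log_L1_quadrature(t, model, GridSpec(n_nodes=401))
        assert abs(a - b) < 1e-6

    def test_quadrature_rotation_invariance(self, model):
        t = random_trials(1, seed=7)[0]
        rot = t.points @ np.array([[0.0, -1.0], [1.0, 0.0]])  # 90 degrees
        assert log_L1_quadrature(rot, model) == pytest.approx(
            log_L1_quadrature(t.points, model), abs=1e-8
        )

    def test_monte_carlo_consistency(self, model, task):
        # L1 is the mean of exp(log joint) over (z, mu) from their priors
        t = random_trials(1, N_range=(5, 5), seed=8)[0]
        rng = np.random.default_rng(9)
        n_samp = 100_000
        mus = rng.normal(0, model.sigma_s, (n_samp, 2))
        zs = rng.uniform(size=(n_samp, t.N)) < 0.5
        d2 = ((t.points[None, :, :] - mus[:, None, :]) ** 2).sum(axis=2)
        log_g = -np.log(2 * np.pi * model.sigma**2) - d2 / (2 * model.sigma**2)
        log_joint = np.where(zs, log_g, -np.log(np.pi * model.R**2)).sum(axis=1)
        vals = np.exp(log_joint)
        est, se = vals.mean(), vals.std(ddof=1) / np.sqrt(n_samp)
        assert abs(est - math.exp(log_L1_exact(t, model))) < 3 * se

    def test_far_point_hurts_less_than_cluster_point_helps(self, model):
        cluster = np.array([[0.5, 0.0], [0.0, 0.5], [-0.4, 0.1]])
        d0 = log_L1_exact(cluster, model) - log_L0(cluster, model)
        with_far = np.vstack([cluster, [9.5, 0.0]])
        with_near = np.vstack([cluster, [0.1, 0.1]])
        d_far = log_L1_exact(with_far, model) - log_L0(with_far, model)
        d_near = log_L1_exact(with_near, model) - log_L0(with_near, model)
        assert d_near - d0 > d_far - d0

    def test_no_overflow_at_extreme_coordinates(self, model):
        rng = np.random.default_rng(10)
        theta = rng.uniform(0, 2 * np.pi, 15)
        x = 9.99 * np.column_stack([np.cos(theta), np.sin(theta)])
        for f in (log_L1_exact, log_L1_quadrature):
            val = f(x, model)
            assert np.isfinite(val)


class TestPosterior:
    def test_two_components_for_single_point(self, model):
        mix = posterior_mu_mixture(np.array([[2.0, 0.0]]), model)
        assert len(mix.log_weights) == 2
        np.testing.assert_allclose(mix.means, [[0, 0], [1, 0]])
        np.testing.assert_allclose(mix.variances, [4.0, 2.0])

    def test_weights_normalise(self, model):
        for t in random_trials(5, seed=11):
            mix = posterior_mu_mixture(t, model)
            assert mix.weights.sum() == pytest.approx(1.0, abs=1e-10)
            assert np.all(mix.variances > 0)

    def test_density_matches_bayes_rule(self, model):
        # mixture density == p(mu) L(mu) / L1 pointwise
        t = random_trials(1, N_range=(4, 4), seed=12)[0]
        mix = posterior_mu_mixture(t, model)
        log_l1 = log_L1_exact(t, model)
        g = np.linspace(-6, 6, 9)
        for mx in g:
            for my in g:
                mu = np.array([mx, my])
                log_prior = -math.log(2 * math.pi * model.sigma_s**2) - (
                    mu @ mu
                ) / (2 * model.sigma_s**2)
                want = math.exp(
                    log_prior + log_L_given_mu(mu, t, model) - log_l1
                )
                got = mix.pdf(mu)
                assert got == pytest.approx(want, rel=1e-8)

    def test_density_integrates_to_one(self, model):
        t = random_trials(1, N_range=(5, 5), seed=13)[0]
        mix = posterior_mu_mixture(t, model)
        g = np.linspace(-12, 12, 241)
        gx, gy = np.meshgrid(g, g, indexing="ij")
        dens = mix.pdf(np.stack([gx, gy], axis=-1))
        mass = np.trapezoid(np.trapezoid(dens, g, axis=1), g)
        assert mass == pytest.approx(1.0, abs=1e-3)

    def test_mean_by_symmetry_and_grid(self, model):
        assert np.allclose(posterior_mean_mu(np.array([[0.0, 0.0]]), model), 0.0)
        x = np.array([[2.0, 0.0]])
        got = posterior_mean_mu(x, model)
        mix = posterior_mu_mixture(x, model)
        g = np.linspace(-12, 12, 481)
        gx, gy = np.meshgrid(g, g, indexing="ij")
        dens = mix.pdf(np.stack([gx, gy], axis=-1))
        ex = np.trapezoid(np.trapezoid(dens * gx, g, axis=1), g)
        ey = np.trapezoid(np.trapezoid(dens * gy, g, axis=1), g)
        np.testing.assert_allclose(got, [ex, ey], atol=1e-4)
        assert got[0] == pytest.approx(0.830, abs=5e-3)
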