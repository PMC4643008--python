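"""MCMC machinery: acceptance rule, conditional updates, full chains."""

import dataclasses

import numpy as np
import pytest

from outclust.data import ConfigError, OutcomeVector, Partition, center_columns
from outclust.model import build_joint_covariance
from outclust.sampler import (
    ChainConfig,
    PriorConfig,
    ProposalConfig,
    SamplerState,
    mh_accept,
    reassign_gene,
    reassignment_logprobs,
    run_chain,
    run_multi_chain,
    sample_betas,
    sample_variance_component,
    sample_weights,
)
from outclust.simulate import SimConfig, simulate_dataset

from conftest import dense_joint_logpdf, make_instance


def _make_state(rng, seed=0, include_outcome=True, **inst_kw):
    Y, Z, params, partition = make_instance(rng, **inst_kw)
    cfg = ChainConfig(
        k_max=partition.k_max,
        iterations=10,
        burn_in=0,
        seed=seed,
        include_outcome=include_outcome,
    )
    state = SamplerState(
        Y,
        Z if include_outcome else None,
        cfg,
        np.random.default_rng(seed),
        labels=partition.assignment,
    )
    return state, Y, Z, params


class TestMhAccept:
    def test_identical_posteriors_always_accept(self, rng):
        assert all(mh_accept(-5.0, -5.0, 0.0, 0.0, rng) for _ in range(100))

    def test_zero_support_always_rejects(self, rng):
        assert not any(
            mh_accept(-np.inf, -5.0, 0.0, 0.0, rng) for _ in range(100)
        )

    def test_empirical_frequency_matches_ratio(self):
        rng = np.random.default_rng(77)
        target = 0.5
        hits = sum(
            mh_accept(np.log(target), 0.0, 0.0, 0.0, rng) for _ in range(10_000)
        )
        assert hits / 10_000 == pytest.approx(0.5, abs=0.02)


class TestSampleWeights:
    def test_symmetric_prior_with_empty_clusters(self):
        rng = np.random.default_rng(5)
        state, *_ = _make_state(np.random.default_rng(1), K=2, J=4)
        state.stats.n = np.zeros(2)
        draws = np.array([sample_weights(state, rng).copy() for _ in range(10_000)])
        np.testing.assert_allclose(draws.mean(axis=0), [0.5, 0.5], atol=0.02)

    def test_posterior_moments(self):
        rng = np.random.default_rng(6)
        state, *_ = _make_state(np.random.default_rng(1), K=3, J=10)
        state.stats.n = np.array([10.0, 0.0, 0.0])
        draws = np.array([sample_weights(state, rng).copy() for _ in range(10_000)])
        np.testing.assert_allclose(
            draws.mean(axis=0), [11 / 13, 1 / 13, 1 / 13], atol=0.02
        )

    def test_draws_on_simplex(self, rng):
        state, *_ = _make_state(np.random.default_rng(2))
        for _ in range(50):
            w = sample_weights(state, rng)
            assert np.all(w > 0)
            assert w.sum() == pytest.approx(1.0, abs=1e-12)


class TestReassignGene:
    def test_symmetric_case_uniform_probabilities(self):
        # with tau tiny the likelihood barely depends on the label, so the
        # multinomial reduces to the (uniform) weights
        rng = np.random.default_rng(3)
        state, *_ = _make_state(rng, K=4, J=6, tau=1e-6)
        state.tau2 = 1e-12
        state.loglik = state._loglik_current()
        logp, _ = reassignment_logprobs(state, 0)
        np.testing.assert_allclose(np.exp(logp), np.full(4, 0.25), atol=1e-6)

    def test_probabilities_sum_to_one(self):
        for seed in range(5):
            state, *_ = _make_state(np.random.default_rng(seed))
            logp, _ = reassignment_logprobs(state, 1)
            assert np.exp(logp).sum() == pytest.approx(1.0, abs=1e-12)

    def test_enumeration_oracle_and_tight_cluster(self):
        # feature deep inside a tight cluster at variance ratio 4: modal
        # label probability > 0.99, verified by independent dense-likelihood
        # enumeration of the K weighted candidates
        sim = SimConfig(
            n_samples=60, n_features=12, true_k=3, cluster_sizes=(4, 4, 4),
            sigma=1.0, tau=2.0, beta=(-5.0, 0.0, 5.0), seed=9,
        )
        Y, Z, truth = simulate_dataset(sim)
        Yc = center_columns(Y)
        cfg = ChainConfig(k_max=3, iterations=10, burn_in=0, seed=1)
        state = SamplerState(
            Yc, Z, cfg, np.random.default_rng(1),
            labels=truth.true_partition.assignment,
        )
        state.sigma2, state.tau2, state.gamma2 = 1.0, 4.0, 1.0
        state.beta = np.array([-5.0, 0.0, 5.0])
        state.loglik = state._loglik_current()
        logp, _ = reassignment_logprobs(state, 0)
        probs = np.exp(logp)
        assert probs[truth.true_partition.assignment[0]] > 0.99
        # enumeration oracle via the dense density
        dense = np.empty(3)
        for k in range(3):
            labels = truth.true_partition.assignment.copy()
            labels[0] = k
            part = Partition(labels, 3)
            cov = build_joint_covariance(state.params(), part)
            dense[k] = np.log(state.omega[k]) + dense_joint_logpdf(Yc, Z, cov)
        dense -= dense.max()
        expected = np.exp(dense) / np.exp(dense).sum()
        np.testing.assert_allclose(probs, expected, rtol=1e-6, atol=1e-12)

    def test_updates_cached_loglik(self):
        state, *_ = _make_state(np.random.default_rng(4))
        for j in range(state.Y.n_features):
            reassign_gene(state, j)
        state.audit()


class TestVarianceUpdates:
    def test_prior_bound_rejects(self):
        rng = np.random.default_rng(0)
        Y, Z, params, partition = make_instance(rng, N=8, J=6, K=2)
        cfg = ChainConfig(
            k_max=2, iterations=10, burn_in=0, seed=0,
            priors=PriorConfig(A=0.01),  # far below the data scale
        )
        state = SamplerState(Y, Z, cfg, rng, labels=partition.assignment)
        state.sigma2 = 0.02**2  # above A^2 already; any proposal near it fails
        state.loglik = state._loglik_current()
        assert not any(
            sample_variance_component(state, "sigma2") for _ in range(50)
        )

    def test_sigma_recovery_with_fixed_partition(self):
        # long run of the sigma^2 update alone on simulated data with the
        # partition held at truth: posterior mean within 3 posterior SDs of 1
        sim = SimConfig(
            n_samples=40, n_features=20, true_k=3, cluster_sizes=(7, 7, 6),
            sigma=1.0, tau=2.0, seed=21,
        )
        Y, Z, truth = simulate_dataset(sim)
        cfg = ChainConfig(k_max=3, iterations=10, burn_in=0, seed=2)
        state = SamplerState(
            center_columns(Y), Z, cfg, np.random.default_rng(2),
            labels=truth.true_partition.assignment,
        )
        state.tau2, state.gamma2 = 4.0, 1.0
        state.beta = np.array([-5.0, 0.0, 5.0])
        state.loglik = state._loglik_current()
        draws = []
        for _ in range(2000):
            sample_variance_component(state, "sigma2")
            draws.append(np.sqrt(state.sigma2))
        draws = np.asarray(draws[500:])
        assert abs(draws.mean() - 1.0) < 3 * draws.std()

    def test_gamma_update_requires_outcome(self):
        state, *_ = _make_state(np.random.default_rng(3), include_outcome=False)
        with pytest.raises(ValueError, match="gamma2"):
            sample_variance_component(state, "gamma2")


class TestSampleBetas:
    def test_recovery_with_fixed_partition(self):
        sim = SimConfig(
            n_samples=60, n_features=21, true_k=3, cluster_sizes=(7, 7, 7),
            sigma=1.0, tau=2.0, beta=(-5.0, 0.0, 5.0), seed=8,
        )
        Y, Z, truth = simulate_dataset(sim)
        cfg = ChainConfig(k_max=3, iterations=10, burn_in=0, seed=3)
        state = SamplerState(
            center_columns(Y), Z, cfg, np.random.default_rng(3),
            labels=truth.true_partition.assignment,
        )
        state.sigma2, state.tau2, state.gamma2 = 1.0, 4.0, 1.0
        state.loglik = state._loglik_current()
        draws = []
        for _ in range(3000):
            sample_betas(state)
            draws.append(state.beta.copy())
        draws = np.asarray(draws[1000:])
        for k, true_b in enumerate([-5.0, 0.0, 5.0]):
            mean, sd = draws[:, k].mean(), draws[:, k].std()
            assert abs(mean - true_b) < 3 * sd, (k, mean, sd)

    def test_proposals_outside_support_rejected(self):
        rng = np.random.default_rng(9)
        Y, Z, params, partition = make_instance(rng, N=8, J=6, K=2)
        cfg = ChainConfig(
            k_max=2, iterations=10, burn_in=0, seed=9,
            priors=PriorConfig(B=0.05),
            proposals=ProposalConfig(beta_step=1.0),
        )
        state = SamplerState(Y, Z, cfg, rng, labels=partition.assignment)
        for _ in range(200):
            sample_betas(state)
            assert np.all(np.abs(state.beta) <= 0.05)

    def test_requires_outcome(self):
        state, *_ = _make_state(np.random.default_rng(1), include_outcome=False)
        with pytest.raises(ValueError, match="beta"):
            sample_betas(state)


class TestRunChain:
    def test_single_iteration_smoke(self, rng):
        Y, Z, _, _ = make_instance(rng, N=6, J=5, K=2)
        cfg = ChainConfig(k_max=2, iterations=1, burn_in=0, seed=0)
        res = run_chain(Y, Z, cfg)
        assert res.assignments.shape == (1, 5)
        Partition(res.assignments[0], 2)  # validates
        assert np.isfinite(res.loglik).all()

    def test_determinism(self, rng):
        Y, Z, _, _ = make_instance(rng, N=8, J=10, K=3)
        cfg = ChainConfig(k_max=3, iterations=30, burn_in=10, seed=42)
        a = run_chain(Y, Z, cfg)
        b = run_chain(Y, Z, cfg)
        np.testing.assert_array_equal(a.assignments, b.assignments)
        np.testing.assert_array_equal(a.sigma, b.sigma)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.loglik, b.loglik)

    def test_burn_in_validation(self):
        with pytest.raises(ConfigError):
            ChainConfig(iterations=10, burn_in=10)

    def test_draws_respect_prior_bounds(self, rng):
        Y, Z, _, _ = make_instance(rng, N=8, J=10, K=3)
        cfg = ChainConfig(
            k_max=3, iterations=60, burn_in=0, seed=5,
            priors=PriorConfig(A=2.0, B=3.0),
        )
        res = run_chain(Y, Z, cfg)
        assert res.sigma.max() < 2.0 and res.tau.max() < 2.0
        assert res.gamma.max() < 2.0
        assert np.abs(res.beta).max() <= 3.0

    def test_expression_only_ignores_outcome(self, rng):
        Y, Z, _, _ = make_instance(rng, N=8, J=10, K=3)
        cfg = ChainConfig(k_max=3, iterations=40, burn_in=0, seed=7,
                          include_outcome=False)
        a = run_chain(Y, None, cfg)
        b = run_chain(Y, OutcomeVector(Z.z * 100 + 3), cfg)
        np.testing.assert_array_equal(a.assignments, b.assignments)
        np.testing.assert_array_equal(a.sigma, b.sigma)
        assert a.beta is None and a.gamma is None

    def test_cached_loglik_consistent_at_end(self, rng):
        from outclust.model import log_joint_density
        from outclust.data import ModelParams

        Y, Z, _, _ = make_instance(rng, N=8, J=10, K=3)
        cfg = ChainConfig(k_max=3, iterations=25, burn_in=0, seed=8)
        res = run_chain(Y, Z, cfg)
        p = ModelParams(
            sigma=res.sigma[-1], tau=res.tau[-1], gamma=res.gamma[-1],
            beta=res.beta[-1], omega=res.omega[-1],
        )
        fresh = log_joint_density(Y, Z, p, Partition(res.assignments[-1], 3))
        assert fresh == pytest.approx(res.loglik[-1], rel=1e-6)


class TestRunMultiChain:
    def test_single_chain_reduction(self, rng):
        Y, Z, _, _ = make_instance(rng, N=6, J=8, K=2)
        cfg = ChainConfig(k_max=2, iterations=15, burn_in=5, seed=11)
        multi = run_multi_chain(Y, Z, cfg, n_chains=1)
        solo = run_chain(Y, Z, cfg)
        np.testing.assert_array_equal(multi[0].assignments, solo.assignments)

    def test_two_chain_concordance_agreement_at_high_ratio(self):
        # the convergence diagnostic: independent chains on well-separated
        # data should produce near-identical concordance matrices
        from outclust.simulate import simulate_dataset, small_three_cluster_config
        from outclust.summaries import chain_agreement, concordance_matrix

        sim = small_three_cluster_config(4.0, seed=19)
        Y, Z, _ = simulate_dataset(sim)
        cfg = ChainConfig(k_max=5, iterations=300, burn_in=150, seed=23)
        chains = run_multi_chain(center_columns(Y), Z, cfg, n_chains=2)
        Ca = concordance_matrix(chains[0].post_burn().assignments)
        Cb = concordance_matrix(chains[1].post_burn().assignments)
        assert chain_agreement(Ca, Cb).correlation > 0.95

    def test_distinct_seeds_distinct_starts(self, rng):
        Y, Z, _, _ = make_instance(rng, N=6, J=20, K=4)
        cfg = ChainConfig(k_max=4, iterations=2, burn_in=0, seed=13)
        chains = run_multi_chain(Y, Z, cfg, n_chains=2)
        assert chains[0].config.seed != chains[1].config.seed
        assert not np.array_equal(
            chains[0].assignments[0], chains[1].assignments[0]
        )
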