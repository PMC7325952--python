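"""Sampler building blocks against independent oracles, plus estimator plumbing."""

import warnings

import numpy as np
import pytest
from scipy import integrate
from scipy.special import expit

from slongdina import SLongDINA, PriorConfig, observed_loglik
from slongdina._sampler import (
    ChainState,
    make_eta_tables,
    make_profiles,
    sample_abilities,
    sample_attribute_profiles,
)


def make_state(lambda0, lambda1, xi, beta, mu, chol, theta, alpha_idx):
    return ChainState(
        lambda0=np.asarray(lambda0, dtype=float),
        lambda1=np.asarray(lambda1, dtype=float),
        xi=np.asarray(xi, dtype=float),
        beta=np.asarray(beta, dtype=float),
        mu=np.asarray(mu, dtype=float),
        chol=np.asarray(chol, dtype=float),
        theta=np.asarray(theta, dtype=float),
        alpha_idx=np.asarray(alpha_idx, dtype=int),
    )


class TestObservedLoglik:
    def test_fully_missing_dataset_gives_zero(self):
        y = np.full((3, 2, 1), np.nan)
        observed = np.zeros_like(y, dtype=bool)
        q = np.ones((1, 2, 1), dtype=np.int8)
        ll = observed_loglik(y, observed, q, np.zeros((1, 2)), np.ones((1, 2)),
                             np.zeros((3, 1, 1), dtype=np.int8))
        assert ll == 0.0

    def test_single_observation_at_half(self):
        y = np.array([[[1.0]]])
        observed = np.ones_like(y, dtype=bool)
        q = np.ones((1, 1, 1), dtype=np.int8)
        alpha = np.zeros((1, 1, 1), dtype=np.int8)  # eta = 0, logit = lambda0 = 0
        ll = observed_loglik(y, observed, q, np.zeros((1, 1)), np.ones((1, 1)), alpha)
        assert ll == pytest.approx(np.log(0.5))

    def test_toy_matches_hand_computed_sum(self):
        # 2 persons, 2 single-attribute items, 1 occasion; hand oracle by loops
        q = np.array([[[1, 0], [0, 1]]], dtype=np.int8)
        lambda0 = np.array([[-1.0, 0.5]])
        lambda1 = np.array([[2.0, 1.0]])
        alpha = np.array([[[1, 0]], [[0, 1]]], dtype=np.int8)  # (N=2, T=1, K=2)
        y = np.array([[[1.0, 0.0]], [[np.nan, 1.0]]]).transpose(0, 2, 1)  # (N, I, T)
        observed = ~np.isnan(y)
        expected = 0.0
        for n in range(2):
            for i in range(2):
                if np.isnan(y[n, i, 0]):
                    continue
                eta = all(alpha[n, 0, k] >= q[0, i, k] for k in range(2))
                p = expit(lambda0[0, i] + lambda1[0, i] * eta)
                expected += np.log(p) if y[n, i, 0] == 1 else np.log(1 - p)
        assert observed_loglik(y, observed, q, lambda0, lambda1, alpha) == pytest.approx(expected)


class TestAttributeGibbs:
    def test_prior_only_draw_is_fair_coin_per_attribute(self):
        # unobserved person-time, theta=0, xi=1.5, beta=0: each bit ~ Bern(0.5)
        n = 40_000
        K = 2
        profiles = make_profiles(K)
        q = np.array([[[1, 0], [0, 1]]], dtype=np.int8)
        state = make_state(
            lambda0=np.zeros((1, 2)), lambda1=np.ones((1, 2)),
            xi=[1.5, 1.5], beta=[0.0, 0.0], mu=[0.0], chol=np.eye(1),
            theta=np.zeros((n, 1)), alpha_idx=np.zeros((n, 1)),
        )
        y_masked = np.zeros((1, n, 2))
        mask_f = np.zeros((1, n, 2))
        sample_attribute_profiles(state, y_masked, mask_f, make_eta_tables(q),
                                  profiles, np.random.default_rng(0))
        bits = profiles[state.alpha_idx[:, 0]]
        se = 0.5 / np.sqrt(n)
        assert np.allclose(bits.mean(axis=0), 0.5, atol=4 * se)

    def test_full_conditional_matches_enumeration_oracle(self):
        # frozen parameters, 1-person problem replicated: empirical profile
        # frequencies must match the brute-force normalized posterior
        n = 100_000
        K = 2
        profiles = make_profiles(K)
        q = np.array([[[1, 0], [1, 1]]], dtype=np.int8)
        lambda0 = np.array([[-1.5, -0.5]])
        lambda1 = np.array([[3.0, 2.0]])
        xi = np.array([1.5, 1.5])
        beta = np.array([-0.5, 0.5])
        theta0 = 0.3
        y_obs = np.array([1.0, 0.0])

        # oracle: enumerate all 4 profiles with explicit loops
        post = np.zeros(4)
        for p_idx in range(4):
            a = [(p_idx >> k) & 1 for k in range(K)]
            lik = 1.0
            for i in range(2):
                eta = all(a[k] >= q[0, i, k] for k in range(K))
                p = expit(lambda0[0, i] + lambda1[0, i] * eta)
                lik *= p if y_obs[i] == 1 else 1 - p
            for k in range(K):
                pk = expit(xi[k] * theta0 - beta[k])
                lik *= pk if a[k] == 1 else 1 - pk
            post[p_idx] = lik
        post /= post.sum()

        state = make_state(
            lambda0=lambda0, lambda1=lambda1, xi=xi, beta=beta,
            mu=[0.0], chol=np.eye(1), theta=np.full((n, 1), theta0),
            alpha_idx=np.zeros((n, 1)),
        )
        y_masked = np.tile(y_obs, (1, n, 1))
        mask_f = np.ones((1, n, 2))
        sample_attribute_profiles(state, y_masked, mask_f, make_eta_tables(q),
                                  profiles, np.random.default_rng(1))
        counts = np.bincount(state.alpha_idx[:, 0], minlength=4)
        chi2 = ((counts - n * post) ** 2 / (n * post)).sum()
        from scipy.stats import chi2 as chi2_dist

        assert counts.sum() == n  # probabilities over all 2^K profiles sum to 1
        assert chi2 < chi2_dist.ppf(0.99, df=3)


class TestAbilityMetropolis:
    def test_prior_recovery_when_attributes_uninformative(self):
        # with xi ~ 0 the stationary distribution of theta is the MVN prior
        n = 4000
        mu = np.array([0.0, 1.0])
        chol = np.linalg.cholesky(np.array([[1.0, 0.6], [0.6, 1.5]]))
        state = make_state(
            lambda0=np.zeros((2, 1)), lambda1=np.ones((2, 1)),
            xi=[1e-9], beta=[0.0], mu=mu, chol=chol,
            theta=np.zeros((n, 2)), alpha_idx=np.zeros((n, 2)),
        )
        profiles = make_profiles(1)
        rng = np.random.default_rng(2)
        for _ in range(600):
            rates = sample_abilities(state, profiles, np.array([1.5, 1.8]), rng)
        assert 0.0 < rates.min() and rates.max() < 1.0
        assert np.allclose(state.theta.mean(axis=0), mu, atol=0.12)
        assert np.allclose(np.cov(state.theta.T), chol @ chol.T, atol=0.2)

    def test_posterior_mean_matches_quadrature_oracle(self):
        # 1-person, T=1 target replicated across persons; quadrature oracle
        xi = np.array([1.5, 1.5, 1.5, 1.5])
        beta = np.array([-1.0, -0.5, 0.5, 1.0])
        a = np.array([1, 1, 0, 0])
        idx = int((a * 2 ** np.arange(4)).sum())

        def log_target(th):
            z = xi * th - beta
            return -0.5 * th**2 + (a * z - np.logaddexp(0, z)).sum()

        grid = np.linspace(-8, 8, 4001)
        dens = np.exp([log_target(t) for t in grid])
        oracle_mean = integrate.trapezoid(grid * dens, grid) / integrate.trapezoid(dens, grid)

        n = 4000
        state = make_state(
            lambda0=np.zeros((1, 1)), lambda1=np.ones((1, 1)),
            xi=xi, beta=beta, mu=[0.0], chol=np.eye(1),
            theta=np.zeros((n, 1)), alpha_idx=np.full((n, 1), idx),
        )
        rng = np.random.default_rng(3)
        profiles = make_profiles(4)
        keep = []
        for sweep in range(500):
            sample_abilities(state, profiles, np.array([1.2]), rng)
            if sweep >= 100:
                keep.append(state.theta[:, 0].copy())
        draws = np.concatenate(keep)
        assert draws.mean() == pytest.approx(oracle_mean, abs=0.02)


class TestSLongDINAFit:
    def test_same_seed_reproducible(self, tiny_dataset):
        kwargs = dict(n_iter=200, burn_in=100, random_state=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = SLongDINA(**kwargs).fit(tiny_dataset.responses, tiny_dataset.q_matrix)
            b = SLongDINA(**kwargs).fit(tiny_dataset.responses, tiny_dataset.q_matrix)
        assert np.array_equal(a.lambda0_, b.lambda0_)
        assert np.array_equal(a.mastery_prob_, b.mastery_prob_)
        assert a.psrf_["psrf"].equals(b.psrf_["psrf"])

    def test_support_constraints_hold_for_every_retained_draw(self, tiny_fit):
        for draws in tiny_fit.draws_:
            assert (draws["lambda1"] > 0).all()
            assert (draws["xi"] > 0).all()
            assert (draws["mu"][:, 0] == 0).all()
            assert np.allclose(draws["sigma"][:, 0, 0], 1.0)
            for sigma in draws["sigma"][::100]:
                np.linalg.cholesky(sigma)  # positive definite

    def test_fitted_attribute_shapes_and_ranges(self, tiny_fit, tiny_dataset):
        N, I, T = tiny_dataset.responses.shape
        K = tiny_dataset.alpha.shape[2]
        assert tiny_fit.lambda0_.shape == (T, I)
        assert tiny_fit.theta_.shape == (N, T)
        assert tiny_fit.mastery_prob_.shape == (N, T, K)
        assert ((tiny_fit.mastery_prob_ >= 0) & (tiny_fit.mastery_prob_ <= 1)).all()
        assert np.array_equal(tiny_fit.alpha_, (tiny_fit.mastery_prob_ >= 0.5))
        assert tiny_fit.predict().shape == (N, T, K)

    def test_classification_tie_counts_as_mastery(self, tiny_fit):
        # the >= 0.5 rule: probability exactly 0.5 classifies as mastered
        assert ((tiny_fit.mastery_prob_ >= 0.5) == tiny_fit.alpha_.astype(bool)).all()

    def test_sklearn_params_roundtrip(self):
        from sklearn.base import clone

        est = SLongDINA(n_iter=123, burn_in=45, priors=PriorConfig(xi_var=2.0))
        cloned = clone(est)
        assert cloned.get_params()["n_iter"] == 123
        assert cloned.priors.xi_var == 2.0

    @pytest.mark.parametrize(
        "kwargs, pattern",
        [
            (dict(n_chains=1), "chains"),
            (dict(burn_in=500, n_iter=100), "burn_in"),
        ],
    )
    def test_config_validation(self, tiny_dataset, kwargs, pattern):
        est = SLongDINA(**{**dict(n_iter=100, burn_in=10), **kwargs})
        with pytest.raises(ValueError, match=pattern):
            est.fit(tiny_dataset.responses, tiny_dataset.q_matrix)

    def test_data_validation(self, tiny_dataset):
        est = SLongDINA(n_iter=100, burn_in=10)
        with pytest.raises(ValueError, match="tensor"):
            est.fit(tiny_dataset.responses[:, :, 0], tiny_dataset.q_matrix)
        bad = tiny_dataset.responses.copy()
        bad[0, 0, 0] = 2.0
        with pytest.raises(ValueError, match="binary"):
            est.fit(bad, tiny_dataset.q_matrix)

    def test_all_missing_occasion_warns(self, tiny_dataset):
        y = tiny_dataset.responses.copy()
        y[:, :, 2] = np.nan
        with pytest.warns(UserWarning, match="no observed responses"):
            SLongDINA(n_iter=60, burn_in=20, random_state=0).fit(
                y, tiny_dataset.q_matrix
            )

    def test_prior_config_rejects_nonpositive_variance(self):
        with pytest.raises(ValueError):
            PriorConfig(xi_var=0.0)
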