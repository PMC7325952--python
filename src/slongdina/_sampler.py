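"""Metropolis-within-Gibbs sampler for the longitudinal higher-order DINA model.

Sweep structure (one iteration):

1. Attribute profiles ``alpha_nt`` — exact Gibbs draw from the full
   conditional by enumerating all 2^K profiles per person-time, combining
   the observed-response likelihood with the higher-order prior given
   ``theta_nt``.  At unobserved person-times the likelihood term is empty and
   the draw follows the structural model alone.
2. Abilities ``theta_nt`` — per-coordinate random-walk Metropolis,
   vectorized across persons, targeting the attribute-level Bernoulli terms
   times the multivariate-normal growth prior.
3. Item parameters ``(lambda0, lambda1)`` — joint random-walk Metropolis per
   item-time against the observed likelihood and the priors; proposals with
   ``lambda1 <= 0`` are rejected.  Anchor items are estimated like any other.
4. Structural parameters — random-walk Metropolis for ``xi_k > 0`` and
   ``beta_k``; for the free growth means ``mu_t`` (t >= 2); and for the free
   elements of the Cholesky factor of ``Sigma`` (the (1,1) element is fixed
   at 1 and ``mu_1`` at 0 for identification, and diagonal proposals <= 0
   are rejected, so every retained ``Sigma`` is positive definite).

Proposal scales are adapted during burn-in toward ~0.3 acceptance and frozen
afterwards.  Missing responses enter nowhere: likelihood sums run over the
observed mask only, so dropped students' post-dropout latents are imputed
from the structural model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "make_profiles",
    "make_eta_tables",
    "observed_loglik",
    "ChainState",
    "sample_attribute_profiles",
    "sample_abilities",
    "sample_item_parameters",
    "sample_structural",
    "run_chain",
]

ADAPT_WINDOW = 50
TARGET_ACCEPT = 0.3


def make_profiles(n_attributes: int) -> np.ndarray:
    """All 2^K binary attribute profiles, shape (2^K, K); bit k = attribute k."""
    p = np.arange(2**n_attributes)
    return ((p[:, None] >> np.arange(n_attributes)) & 1).astype(np.int8)


def make_eta_tables(q_entries: np.ndarray) -> np.ndarray:
    """Conjunction indicator for every (profile, item): shape (T, 2^K, I)."""
    T, I, K = q_entries.shape
    profiles = make_profiles(K)
    tabs = np.empty((T, 2**K, I), dtype=np.int8)
    for t in range(T):
        required = q_entries[t].sum(axis=1)
        tabs[t] = profiles @ q_entries[t].T == required[None, :]
    return tabs


def _softplus(z):
    return np.logaddexp(0.0, z)


def observed_loglik(responses, observed, q_entries, lambda0, lambda1, alpha):
    """Bernoulli log-likelihood summed over observed person-item-times only.

    ``responses`` is (N, I, T) (NaN allowed at unobserved entries),
    ``observed`` the parallel boolean mask, ``alpha`` (N, T, K).  An entirely
    missing dataset returns exactly 0 (the empty sum).
    """
    responses = np.asarray(responses, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    q_entries = np.asarray(q_entries)
    T = q_entries.shape[0]
    total = 0.0
    for t in range(T):
        eta = np.all(alpha[:, t, None, :] >= q_entries[t][None, :, :], axis=2)
        z = lambda0[t][None, :] + lambda1[t][None, :] * eta
        y = np.where(observed[:, :, t], responses[:, :, t], 0.0)
        ll = y * z - observed[:, :, t] * _softplus(z)
        total += float(ll.sum())
    return total


@dataclass
class ChainState:
    """Mutable state of one Markov chain (internal layout: time-major data)."""

    lambda0: np.ndarray  # (T, I)
    lambda1: np.ndarray  # (T, I)
    xi: np.ndarray  # (K,)
    beta: np.ndarray  # (K,)
    mu: np.ndarray  # (T,), mu[0] == 0
    chol: np.ndarray  # (T, T) lower triangular, chol[0, 0] == 1
    theta: np.ndarray  # (N, T)
    alpha_idx: np.ndarray  # (N, T) ints in [0, 2^K)

    def __post_init__(self):
        self.refresh_sigma()

    def refresh_sigma(self):
        self.sigma = self.chol @ self.chol.T
        self.precision = np.linalg.inv(self.sigma)
        self.logdet = 2.0 * float(np.log(np.diag(self.chol)).sum())


def _mvn_loglik(theta, mu, precision, logdet):
    d = theta - mu[None, :]
    return -0.5 * theta.shape[0] * logdet - 0.5 * float(
        np.einsum("nt,ts,ns->", d, precision, d)
    )


def sample_attribute_profiles(state, y_masked, mask_f, eta_tables, profiles, rng):
    """Exact Gibbs update of all attribute profiles (in place).

    ``y_masked``/``mask_f`` are (T, N, I) float arrays with unobserved
    entries zeroed, so the matmuls below sum log-Bernoulli terms over
    observed responses only.
    """
    T = state.theta.shape[1]
    for t in range(T):
        z = state.lambda0[t][None, :] + state.lambda1[t][None, :] * eta_tables[t]
        sp = _softplus(z)  # (P, I)
        loglik = y_masked[t] @ z.T - mask_f[t] @ sp.T  # (N, P)
        zk = state.xi[None, :] * state.theta[:, t, None] - state.beta[None, :]
        logprior = zk @ profiles.T.astype(float) - _softplus(zk).sum(axis=1, keepdims=True)
        g = rng.gumbel(size=loglik.shape)
        state.alpha_idx[:, t] = np.argmax(loglik + logprior + g, axis=1)


def sample_abilities(state, profiles, scales, rng):
    """Per-coordinate random-walk Metropolis on theta; returns acceptance rates."""
    N, T = state.theta.shape
    A = profiles[state.alpha_idx].astype(float)  # (N, T, K)
    acc_rates = np.empty(T)
    for t in range(T):
        cur = state.theta[:, t]
        prop = cur + scales[t] * rng.standard_normal(N)
        zc = state.xi[None, :] * cur[:, None] - state.beta[None, :]
        zp = state.xi[None, :] * prop[:, None] - state.beta[None, :]
        Ak = A[:, t, :]
        ll_diff = ((Ak * (zp - zc)) - (_softplus(zp) - _softplus(zc))).sum(axis=1)
        # MVN prior: only coordinate t of the quadratic form changes
        d = state.theta - state.mu[None, :]
        ptt = state.precision[t, t]
        r = d @ state.precision[:, t] - ptt * d[:, t]
        dc = cur - state.mu[t]
        dp = prop - state.mu[t]
        prior_diff = -(0.5 * ptt * (dp**2 - dc**2) + (dp - dc) * r)
        accept = np.log(rng.random(N)) < ll_diff + prior_diff
        state.theta[accept, t] = prop[accept]
        acc_rates[t] = accept.mean()
    return acc_rates


def sample_item_parameters(state, y_masked, mask_f, eta_tables, priors, scales0, scales1, rng):
    """Joint (lambda0, lambda1) random-walk Metropolis per item-time."""
    T, I = state.lambda0.shape
    eta = np.stack(
        [eta_tables[t][state.alpha_idx[:, t], :] for t in range(T)]
    ).astype(float)  # (T, N, I)
    z = state.lambda0[:, None, :] + state.lambda1[:, None, :] * eta
    ll_cur = (y_masked * z - mask_f * _softplus(z)).sum(axis=1)  # (T, I)
    l0p = state.lambda0 + scales0 * rng.standard_normal((T, I))
    l1p = state.lambda1 + scales1 * rng.standard_normal((T, I))
    zp = l0p[:, None, :] + l1p[:, None, :] * eta
    ll_prop = (y_masked * zp - mask_f * _softplus(zp)).sum(axis=1)
    prior_diff = (
        (state.lambda0 - priors.lambda0_mean) ** 2 - (l0p - priors.lambda0_mean) ** 2
    ) / (2 * priors.lambda0_var) + (
        (state.lambda1 - priors.lambda1_mean) ** 2 - (l1p - priors.lambda1_mean) ** 2
    ) / (2 * priors.lambda1_var)
    logacc = ll_prop - ll_cur + prior_diff
    accept = (np.log(rng.random((T, I))) < logacc) & (l1p > 0)
    state.lambda0[accept] = l0p[accept]
    state.lambda1[accept] = l1p[accept]
    return accept.mean(axis=1)  # per time point


def sample_structural(state, profiles, priors, scales, rng):
    """Metropolis updates for xi, beta, free mu coordinates, and Sigma's Cholesky."""
    N, T = state.theta.shape
    K = state.xi.size
    A = profiles[state.alpha_idx].astype(float)  # (N, T, K)
    acc = {}

    def attr_loglik(xi, beta):
        z = xi[None, None, :] * state.theta[:, :, None] - beta[None, None, :]
        return (A * z - _softplus(z)).sum(axis=(0, 1))  # (K,)

    ll_cur = attr_loglik(state.xi, state.beta)
    # slopes (truncated > 0; truncation constant cancels between proposals)
    xi_p = state.xi + scales["xi"] * rng.standard_normal(K)
    ll_p = attr_loglik(xi_p, state.beta)
    prior = ((state.xi - priors.xi_mean) ** 2 - (xi_p - priors.xi_mean) ** 2) / (
        2 * priors.xi_var
    )
    keep = (np.log(rng.random(K)) < ll_p - ll_cur + prior) & (xi_p > 0)
    state.xi[keep] = xi_p[keep]
    acc["xi"] = keep.mean()
    ll_cur = np.where(keep, ll_p, ll_cur)
    # difficulties
    beta_p = state.beta + scales["beta"] * rng.standard_normal(K)
    ll_p = attr_loglik(state.xi, beta_p)
    prior = ((state.beta - priors.beta_mean) ** 2 - (beta_p - priors.beta_mean) ** 2) / (
        2 * priors.beta_var
    )
    keep = np.log(rng.random(K)) < ll_p - ll_cur + prior
    state.beta[keep] = beta_p[keep]
    acc["beta"] = keep.mean()

    # growth means, mu[0] fixed at 0 for identification
    mvn_cur = _mvn_loglik(state.theta, state.mu, state.precision, state.logdet)
    n_acc = 0
    for t in range(1, T):
        mu_p = state.mu.copy()
        mu_p[t] += scales["mu"][t - 1] * rng.standard_normal()
        mvn_p = _mvn_loglik(state.theta, mu_p, state.precision, state.logdet)
        prior = (
            (state.mu[t] - priors.mu_mean) ** 2 - (mu_p[t] - priors.mu_mean) ** 2
        ) / (2 * priors.mu_var)
        if np.log(rng.random()) < mvn_p - mvn_cur + prior:
            state.mu = mu_p
            mvn_cur = mvn_p
            n_acc += 1
    acc["mu"] = n_acc / max(T - 1, 1)

    # covariance via its Cholesky factor; (0, 0) element fixed at 1
    free = [(r, c) for r in range(1, T) for c in range(r + 1)]
    n_acc = 0
    for j, (r, c) in enumerate(free):
        chol_p = state.chol.copy()
        chol_p[r, c] += scales["chol"][j] * rng.standard_normal()
        if r == c and chol_p[r, c] <= 1e-8:
            continue  # automatic rejection keeps Sigma positive definite
        sigma_p = chol_p @ chol_p.T
        prec_p = np.linalg.inv(sigma_p)
        logdet_p = 2.0 * float(np.log(np.diag(chol_p)).sum())
        mvn_p = _mvn_loglik(state.theta, state.mu, prec_p, logdet_p)
        prior = (
            (state.chol[r, c] - priors.chol_mean) ** 2
            - (chol_p[r, c] - priors.chol_mean) ** 2
        ) / (2 * priors.chol_var)
        if np.log(rng.random()) < mvn_p - mvn_cur + prior:
            state.chol = chol_p
            state.sigma = sigma_p
            state.precision = prec_p
            state.logdet = logdet_p
            mvn_cur = mvn_p
            n_acc += 1
    acc["chol"] = n_acc / len(free)
    return acc


def initial_state(n_persons, q_entries, rng) -> ChainState:
    """Dispersed random starting point for one chain."""
    T, I, K = q_entries.shape
    chol = np.eye(T)
    for r in range(1, T):
        chol[r, :r] = rng.normal(0.0, 0.5, r)
        chol[r, r] = np.exp(rng.normal(0.0, 0.3))
    mu = np.concatenate([[0.0], rng.normal(0.0, 2.0, T - 1)])
    return ChainState(
        lambda0=rng.normal(-1.0, 1.5, (T, I)),
        lambda1=rng.uniform(0.5, 5.0, (T, I)),
        xi=rng.uniform(0.5, 3.0, K),
        beta=rng.normal(0.0, 1.5, K),
        mu=mu,
        chol=chol,
        theta=mu[None, :] + rng.standard_normal((n_persons, T)),
        alpha_idx=rng.integers(0, 2**K, (n_persons, T)),
    )


class _Adapter:
    """Multiplicative proposal-scale adaptation toward TARGET_ACCEPT."""

    def __init__(self, scale):
        self.scale = scale
        self._sum = 0.0
        self._n = 0

    def record(self, rate):
        self._sum += np.mean(rate)
        self._n += 1

    def adapt(self):
        if self._n == 0:
            return
        rate = self._sum / self._n
        self.scale = self.scale * float(
            np.clip(np.exp(0.8 * (rate - TARGET_ACCEPT)), 0.5, 2.0)
        )
        self._sum = 0.0
        self._n = 0


def run_chain(
    responses,
    observed,
    q_entries,
    priors,
    n_iter,
    burn_in,
    thin,
    rng,
    adapt=True,
    store_theta=True,
):
    """Run one chain; returns (draws dict, alpha posterior-mean, acceptance dict).

    ``responses``/``observed`` use the public (N, I, T) layout.  Kept draws
    are the post-burn-in iterations at the given thinning.
    """
    responses = np.asarray(responses, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    N, I, T = responses.shape
    K = q_entries.shape[2]
    P = 2**K
    profiles = make_profiles(K)
    eta_tables = make_eta_tables(q_entries)
    # time-major masked copies: matmuls then sum over observed entries only
    y_masked = np.ascontiguousarray(
        np.where(observed, responses, 0.0).transpose(2, 0, 1)
    )
    mask_f = np.ascontiguousarray(observed.transpose(2, 0, 1).astype(float))

    state = initial_state(N, q_entries, rng)
    scales = {
        "theta": _Adapter(np.full(T, 0.8)),
        "item0": _Adapter(np.full((T, I), 0.3)),
        "item1": _Adapter(np.full((T, I), 0.5)),
        "xi": _Adapter(np.full(state.xi.size, 0.25)),
        "beta": _Adapter(np.full(state.beta.size, 0.25)),
        "mu": _Adapter(np.full(max(T - 1, 1), 0.15)),
        "chol": _Adapter(np.full(T * (T + 1) // 2 - 1, 0.1)),
    }

    n_kept = (n_iter - burn_in) // thin
    if n_kept <= 0:
        raise ValueError("no draws kept: check iterations/burn_in/thin")
    draws = {
        "lambda0": np.empty((n_kept, T, I)),
        "lambda1": np.empty((n_kept, T, I)),
        "xi": np.empty((n_kept, K)),
        "beta": np.empty((n_kept, K)),
        "mu": np.empty((n_kept, T)),
        "sigma": np.empty((n_kept, T, T)),
    }
    if store_theta:
        draws["theta"] = np.empty((n_kept, N, T), dtype=np.float32)
    alpha_sum = np.zeros((N, T, K))
    acc_log = {k: [] for k in scales}

    kept = 0
    for it in range(n_iter):
        sample_attribute_profiles(state, y_masked, mask_f, eta_tables, profiles, rng)
        a_th = sample_abilities(state, profiles, scales["theta"].scale, rng)
        a_it = sample_item_parameters(
            state,
            y_masked,
            mask_f,
            eta_tables,
            priors,
            scales["item0"].scale,
            scales["item1"].scale,
            rng,
        )
        a_st = sample_structural(
            state,
            profiles,
            priors,
            {
                "xi": scales["xi"].scale,
                "beta": scales["beta"].scale,
                "mu": scales["mu"].scale,
                "chol": scales["chol"].scale,
            },
            rng,
        )
        if adapt and it < burn_in:
            scales["theta"].record(a_th)
            scales["item0"].record(a_it)
            scales["item1"].record(a_it)
            scales["xi"].record(a_st["xi"])
            scales["beta"].record(a_st["beta"])
            scales["mu"].record(a_st["mu"])
            scales["chol"].record(a_st["chol"])
            if (it + 1) % ADAPT_WINDOW == 0:
                for ad in scales.values():
                    ad.adapt()
        for key, val in zip(
            scales, (a_th, a_it, a_it, a_st["xi"], a_st["beta"], a_st["mu"], a_st["chol"])
        ):
            acc_log[key].append(np.mean(val))
        if it >= burn_in and (it - burn_in) % thin == 0:
            draws["lambda0"][kept] = state.lambda0
            draws["lambda1"][kept] = state.lambda1
            draws["xi"][kept] = state.xi
            draws["beta"][kept] = state.beta
            draws["mu"][kept] = state.mu
            draws["sigma"][kept] = state.sigma
            if store_theta:
                draws["theta"][kept] = state.theta
            alpha_sum += profiles[state.alpha_idx]
            kept += 1

    acceptance = {k: float(np.mean(v)) for k, v in acc_log.items()}
    return draws, alpha_sum / max(kept, 1), acceptance
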