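"""Core probability model for the simplified longitudinal higher-order DINA model.

The model has three levels:

1. *Measurement* — a DINA (deterministic-inputs, noisy "and" gate) item
   response function.  Person ``n`` answers item ``i`` at time point ``t``
   correctly with probability

   ``logit P(y_nit = 1) = lambda0_it + lambda1_it * eta_nit``

   where ``eta_nit`` is the conjunction indicator: 1 iff the person masters
   every attribute the Q-matrix requires for that item.

2. *Attribute structure* — mastery of attribute ``k`` at time ``t`` is driven
   by a time-specific general ability ``theta_nt``:

   ``logit P(alpha_nkt = 1) = xi_k * theta_nt - beta_k``

   with slope ``xi_k > 0`` and difficulty ``beta_k`` shared across time
   points (the same latent structure is measured at every occasion).

3. *Growth* — the ability vector ``theta_n = (theta_n1, ..., theta_nT)`` is
   multivariate normal with mean ``mu`` and covariance ``Sigma``.  For
   identification the first occasion is standard normal: ``mu_1 = 0`` and
   ``Sigma_11 = 1``.

This module holds the parameter containers shared by the rest of the package
and the model equations as pure functions.  Everything here is free of
randomness and I/O.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "QMatrix",
    "ItemParameters",
    "StructuralParameters",
    "conjunction_indicator",
    "response_probability",
    "mastery_probability",
    "build_covariance",
]


@dataclass(frozen=True)
class QMatrix:
    """Per-time-point binary item-by-attribute loading structure.

    Parameters
    ----------
    entries
        Binary array of shape ``(T, I, K)``: ``entries[t, i, k] = 1`` if item
        ``i`` requires attribute ``k`` at time point ``t``.
    anchor_count
        Number of anchor items.  Anchors are the first ``anchor_count`` items
        at every time point and must load identically across time points
        (they link the scale across occasions).
    """

    entries: np.ndarray
    anchor_count: int = 0

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries)
        if entries.ndim != 3:
            raise ValueError("Q-matrix entries must have shape (T, I, K)")
        if not np.isin(entries, (0, 1)).all():
            raise ValueError("Q-matrix entries must be binary")
        entries = entries.astype(np.int8)
        if (entries.sum(axis=2) < 1).any():
            raise ValueError("every item must require at least one attribute")
        if (entries.sum(axis=1) < 1).any():
            raise ValueError(
                "every attribute must be measured by at least one item "
                "at every time point"
            )
        if not 0 <= self.anchor_count <= entries.shape[1]:
            raise ValueError("anchor_count outside [0, I]")
        anchors = entries[:, : self.anchor_count, :]
        if self.anchor_count and not (anchors == anchors[0]).all():
            raise ValueError("anchor rows must be identical across time points")
        object.__setattr__(self, "entries", entries)

    @property
    def n_times(self) -> int:
        return self.entries.shape[0]

    @property
    def n_items(self) -> int:
        return self.entries.shape[1]

    @property
    def n_attributes(self) -> int:
        return self.entries.shape[2]


@dataclass(frozen=True)
class ItemParameters:
    """DINA item intercepts and interactions on the logit scale.

    ``lambda0`` (intercept) controls the guessing probability
    ``expit(lambda0)``; ``lambda0 + lambda1`` controls the non-slipping
    probability.  ``lambda1 > 0`` enforces monotonicity: mastering the
    required attributes never lowers the success probability.
    Both arrays have shape ``(T, I)``.
    """

    lambda0: np.ndarray
    lambda1: np.ndarray

    def __post_init__(self) -> None:
        lambda0 = np.asarray(self.lambda0, dtype=float)
        lambda1 = np.asarray(self.lambda1, dtype=float)
        if lambda0.shape != lambda1.shape or lambda0.ndim != 2:
            raise ValueError("lambda0 and lambda1 must both have shape (T, I)")
        if not (lambda1 > 0).all():
            raise ValueError("interaction parameters lambda1 must be > 0")
        object.__setattr__(self, "lambda0", lambda0)
        object.__setattr__(self, "lambda1", lambda1)


@dataclass(frozen=True)
class StructuralParameters:
    """Higher-order attribute-structure and growth parameters.

    ``xi`` (per-attribute slope, positive) and ``beta`` (per-attribute
    difficulty) are shared across time points; ``mu``/``sigma`` are the mean
    and covariance of the ability vector across the ``T`` occasions, with the
    identification constraints ``mu[0] == 0`` and ``sigma[0, 0] == 1``.
    """

    xi: np.ndarray
    beta: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        xi = np.asarray(self.xi, dtype=float)
        beta = np.asarray(self.beta, dtype=float)
        mu = np.asarray(self.mu, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if xi.shape != beta.shape or xi.ndim != 1:
            raise ValueError("xi and beta must be 1-d arrays of length K")
        if not (xi > 0).all():
            raise ValueError("attribute slopes xi must be > 0")
        if mu.ndim != 1 or sigma.shape != (mu.size, mu.size):
            raise ValueError("mu must be length T and sigma T-by-T")
        if abs(mu[0]) > 1e-12:
            raise ValueError("identification requires mu[0] == 0")
        if abs(sigma[0, 0] - 1.0) > 1e-12:
            raise ValueError("identification requires sigma[0, 0] == 1")
        if not np.allclose(sigma, sigma.T):
            raise ValueError("sigma must be symmetric")
        try:
            np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError as err:
            raise ValueError("sigma must be positive definite") from err
        object.__setattr__(self, "xi", xi)
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)

    @property
    def n_attributes(self) -> int:
        return self.xi.size

    @property
    def n_times(self) -> int:
        return self.mu.size


def conjunction_indicator(alpha_row: np.ndarray, q_row: np.ndarray) -> np.ndarray:
    """DINA conjunction: 1 iff every attribute required by ``q_row`` is mastered.

    Both arguments are binary arrays whose last axis has length ``K``;
    broadcasting over leading axes is supported.  An all-zero requirement row
    returns 1 (the empty-product convention), keeping the function total even
    though simulated Q-matrices never contain such rows.
    """
    alpha_row = np.asarray(alpha_row)
    q_row = np.asarray(q_row)
    if alpha_row.shape[-1] != q_row.shape[-1]:
        raise ValueError(
            f"attribute profile length {alpha_row.shape[-1]} does not match "
            f"Q-matrix row length {q_row.shape[-1]}"
        )
    eta = np.all((alpha_row >= q_row) | (q_row == 0), axis=-1)
    return eta.astype(np.int8)


def response_probability(eta, lambda0, lambda1):
    """Probability of a correct response given the conjunction indicator.

    ``expit(lambda0 + lambda1 * eta)``, strictly inside (0, 1) for finite
    parameters.  ``lambda1`` must be positive (monotonicity).
    """
    lambda1 = np.asarray(lambda1, dtype=float)
    if not (lambda1 > 0).all():
        raise ValueError("lambda1 must be > 0")
    return expit(np.asarray(lambda0, dtype=float) + lambda1 * np.asarray(eta))


def mastery_probability(theta, xi_k, beta_k):
    """Probability of mastering an attribute given general ability.

    ``expit(xi_k * theta - beta_k)``; increasing in ``theta`` for positive
    slope ``xi_k``, decreasing in the difficulty ``beta_k``.
    """
    xi_k = np.asarray(xi_k, dtype=float)
    if not (xi_k > 0).all():
        raise ValueError("xi must be > 0")
    return expit(xi_k * np.asarray(theta, dtype=float) - np.asarray(beta_k, dtype=float))


def build_covariance(sds, rho: float) -> np.ndarray:
    """Equicorrelated covariance matrix from per-occasion SDs.

    ``Sigma[t, t] = sds[t]**2`` and ``Sigma[t, s] = rho * sds[t] * sds[s]``
    for ``t != s``.  Positive definiteness of the equicorrelation structure
    requires ``-1/(T-1) < rho < 1`` (for T = 2 this is just ``|rho| < 1``).
    """
    sds = np.asarray(sds, dtype=float)
    if sds.ndim != 1 or not (sds > 0).all():
        raise ValueError("sds must be a 1-d array of positive reals")
    lower = -1.0 / max(sds.size - 1, 1)
    if not lower < rho < 1:
        raise ValueError(f"rho must lie in ({lower:.4g}, 1) for {sds.size} occasions")
    corr = np.full((sds.size, sds.size), rho)
    np.fill_diagonal(corr, 1.0)
    sigma = corr * np.outer(sds, sds)
    # impossible under the preconditions; guards numerical pathologies
    try:
        np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as err:  # pragma: no cover
        raise RuntimeError("constructed covariance is not positive definite") from err
    return sigma
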