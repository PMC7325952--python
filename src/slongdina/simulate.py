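"""Synthetic data generation for the longitudinal attrition simulation study.

Generates complete response datasets from the simplified longitudinal
higher-order DINA model under the study's generating conditions, then injects
individual-level random attrition (monotone dropout: once a student misses a
time point they never return).

Generating conditions
---------------------
* T = 3 occasions, K = 4 attributes, N in {200, 400}, I_t in {15, 30}.
* Anchor items (first 4 of 15 or first 8 of 30) have fixed high-quality
  parameters lambda0 = -2.197, lambda1 = 4.394, i.e. guessing and slipping
  probabilities of about 0.1.
* Non-anchor item parameters are bivariate normal with mean (-2.197, 4.394),
  unit variances and correlation -0.6 (negatively related guessing and
  slipping), rejection-sampled to keep lambda1 > 0.
* Attribute slopes xi_k = 1.5; difficulties beta = (-1, -0.5, 0.5, 1).
* Abilities are MVN with means (0, 1, 2) (unit mean growth per step),
  SDs (1, 1.25, 1.5625) (scale ratio 1.25 per step) and cross-occasion
  correlation 0.9.
* Attrition: from time point 2, at each occasion a fraction M1 of the
  *remaining* students is sampled uniformly and dropped; fractional counts
  are truncated (floor).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    ItemParameters,
    QMatrix,
    StructuralParameters,
    build_covariance,
    conjunction_indicator,
    mastery_probability,
    response_probability,
)

__all__ = [
    "GeneratingConfig",
    "SimulatedDataset",
    "build_q_matrix",
    "generate_item_parameters",
    "generate_abilities",
    "generate_attributes",
    "generate_responses",
    "apply_attrition",
    "simulate_dataset",
    "write_responses_csv",
    "read_responses_csv",
    "write_q_matrix_csv",
    "read_q_matrix_csv",
    "write_truth_json",
]

ANCHOR_LAMBDA0 = -2.197
ANCHOR_LAMBDA1 = 4.394
NONANCHOR_MEAN = (ANCHOR_LAMBDA0, ANCHOR_LAMBDA1)
NONANCHOR_COV = ((1.0, -0.6), (-0.6, 1.0))


@dataclass(frozen=True)
class GeneratingConfig:
    """Study generating conditions; defaults are the baseline short-test cell."""

    n_persons: int = 200
    items_per_time: int = 15
    n_times: int = 3
    n_attributes: int = 4
    attrition_rate: float = 0.0
    xi: tuple = (1.5, 1.5, 1.5, 1.5)
    beta: tuple = (-1.0, -0.5, 0.5, 1.0)
    mean_growth: float = 1.0
    scale_ratio: float = 1.25
    rho: float = 0.9
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.attrition_rate < 1:
            raise ValueError("attrition_rate must lie in [0, 1)")
        if min(self.n_persons, self.items_per_time, self.n_times, self.n_attributes) < 1:
            raise ValueError("all dimensions must be positive")
        if len(self.xi) != self.n_attributes or len(self.beta) != self.n_attributes:
            raise ValueError("xi and beta must have one entry per attribute")

    @property
    def anchor_count(self) -> int:
        # 4 anchors for the 15-item tests, 8 for the 30-item tests
        return 4 if self.items_per_time <= 15 else 8

    def structural_parameters(self) -> StructuralParameters:
        t = np.arange(self.n_times)
        mu = self.mean_growth * t
        sds = self.scale_ratio**t
        return StructuralParameters(
            xi=np.asarray(self.xi, dtype=float),
            beta=np.asarray(self.beta, dtype=float),
            mu=mu.astype(float),
            sigma=build_covariance(sds, self.rho),
        )


@dataclass
class SimulatedDataset:
    """A simulated response tensor plus the complete generating truth.

    ``responses`` has shape ``(N, I, T)`` with ``np.nan`` at unobserved
    person-item-times; ``observed`` is the parallel boolean mask.
    ``dropout_time`` holds, per person, the last (1-based) occasion at which
    the person is observed (``T`` for completers).  The truth — including
    abilities and attribute profiles of dropped students at unobserved
    occasions — is always retained so recovery can be scored for everyone.
    """

    responses: np.ndarray
    observed: np.ndarray
    dropout_time: np.ndarray
    q_matrix: QMatrix
    items: ItemParameters
    structural: StructuralParameters
    theta: np.ndarray  # (N, T)
    alpha: np.ndarray  # (N, T, K)
    config: GeneratingConfig | None = None

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def n_times(self) -> int:
        return self.responses.shape[2]

    def observed_persons(self) -> np.ndarray:
        """Boolean (N, T): person observed at occasion t."""
        return self.observed.any(axis=1)


def build_q_matrix(
    items_per_time: int,
    n_attributes: int = 4,
    n_times: int = 3,
    anchor_count: int | None = None,
) -> QMatrix:
    """Deterministic Q-matrix with anchors and identifiability guarantees.

    The construction satisfies, at every time point: anchor rows identical
    across occasions; every attribute measured by at least one
    single-attribute item (completeness) and by at least three items in
    total; a mix of one- and two-attribute items.  Non-anchor rows have
    their attribute labels cyclically rotated across time points so the
    occasion-specific forms differ while preserving the constraints.
    """
    K = n_attributes
    if anchor_count is None:
        anchor_count = 4 if items_per_time <= 15 else 8
    if anchor_count % K != 0 or anchor_count < K:
        raise ValueError("anchor_count must be a positive multiple of n_attributes")
    n_free = items_per_time - anchor_count
    if n_free < K + 3:
        raise ValueError(
            f"cannot build a valid Q-matrix with {items_per_time} items, "
            f"{K} attributes and {anchor_count} anchors"
        )

    singles = np.eye(K, dtype=np.int8)
    pair_rows = []
    for a, b in combinations(range(K), 2):
        row = np.zeros(K, dtype=np.int8)
        row[[a, b]] = 1
        pair_rows.append(row)
    pair_rows = np.array(pair_rows)

    anchors = np.vstack([singles] * (anchor_count // K))
    # non-anchors: one full cycle of singles per 15 items, pairs for the rest
    n_single_free = K * max(1, n_free // 11)
    n_pairs = n_free - n_single_free
    free_singles = np.vstack([singles] * (n_single_free // K))
    free_pairs = pair_rows[np.arange(n_pairs) % len(pair_rows)]
    base_free = np.vstack([free_singles, free_pairs])

    entries = np.empty((n_times, items_per_time, K), dtype=np.int8)
    for t in range(n_times):
        rotated = np.roll(base_free, shift=t, axis=1)  # relabel attributes
        entries[t] = np.vstack([anchors, rotated])

    q = QMatrix(entries=entries, anchor_count=anchor_count)
    if (q.entries.sum(axis=1) < 3).any():
        raise ValueError("constructed Q-matrix measures some attribute < 3 times")
    return q


def generate_item_parameters(q_matrix: QMatrix, rng: np.random.Generator) -> ItemParameters:
    """Fixed anchor parameters; bivariate-normal non-anchor parameters.

    Non-anchor ``(lambda0, lambda1)`` pairs are drawn independently per
    item-time from ``MVN((-2.197, 4.394), [[1, -0.6], [-0.6, 1]])``; draws
    with non-positive interaction are rejected and redrawn so monotonicity
    holds by construction.
    """
    T, I = q_matrix.n_times, q_matrix.n_items
    lambda0 = np.full((T, I), ANCHOR_LAMBDA0)
    lambda1 = np.full((T, I), ANCHOR_LAMBDA1)
    n_free = I - q_matrix.anchor_count
    if n_free:
        draws = rng.multivariate_normal(NONANCHOR_MEAN, NONANCHOR_COV, size=(T, n_free))
        bad = draws[..., 1] <= 0
        while bad.any():  # rejection is ~1e-5 per draw with these settings
            redraw = rng.multivariate_normal(NONANCHOR_MEAN, NONANCHOR_COV, size=int(bad.sum()))
            draws[bad] = redraw
            bad = draws[..., 1] <= 0
        lambda0[:, q_matrix.anchor_count :] = draws[..., 0]
        lambda1[:, q_matrix.anchor_count :] = draws[..., 1]
    return ItemParameters(lambda0=lambda0, lambda1=lambda1)


def generate_abilities(
    n_persons: int, structural: StructuralParameters, rng: np.random.Generator
) -> np.ndarray:
    """Draw N ability trajectories from MVN(mu, Sigma); shape (N, T)."""
    return rng.multivariate_normal(structural.mu, structural.sigma, size=n_persons)


def generate_attributes(
    theta: np.ndarray, structural: StructuralParameters, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli attribute profiles given abilities; shape (N, T, K)."""
    p = mastery_probability(
        theta[:, :, None], structural.xi[None, None, :], structural.beta[None, None, :]
    )
    return (rng.random(p.shape) < p).astype(np.int8)


def generate_responses(
    alpha: np.ndarray,
    q_matrix: QMatrix,
    items: ItemParameters,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bernoulli DINA responses given attribute profiles; shape (N, I, T)."""
    N, T, _ = alpha.shape
    responses = np.empty((N, q_matrix.n_items, T))
    for t in range(T):
        eta = conjunction_indicator(alpha[:, t, None, :], q_matrix.entries[t][None, :, :])
        p = response_probability(eta, items.lambda0[t][None, :], items.lambda1[t][None, :])
        responses[:, :, t] = rng.random(p.shape) < p
    return responses


def apply_attrition(
    data: SimulatedDataset, attrition_rate: float, rng: np.random.Generator
) -> SimulatedDataset:
    """Inject individual-level random monotone dropout.

    From time point 2 onward, ``floor(attrition_rate * n_active)`` of the
    students still in the study are sampled uniformly at random and marked
    unobserved from that occasion on (fractional counts truncated).  The
    generating truth is untouched; only the observation mask and the response
    values at unobserved person-times change (set to NaN).
    """
    if not 0 <= attrition_rate < 1:
        raise ValueError("attrition_rate must lie in [0, 1)")
    N, _, T = data.responses.shape
    responses = data.responses.copy()
    observed = data.observed.copy()
    dropout_time = data.dropout_time.copy()
    active = np.flatnonzero(dropout_time == T)
    for t in range(1, T):
        n_drop = int(np.floor(attrition_rate * active.size))
        if n_drop == 0:
            continue
        dropped = rng.choice(active, size=n_drop, replace=False)
        dropout_time[dropped] = t  # last observed occasion, 1-based
        observed[dropped, :, t:] = False
        responses[dropped, :, t:] = np.nan
        active = np.setdiff1d(active, dropped, assume_unique=True)
    return dataclasses.replace(
        data, responses=responses, observed=observed, dropout_time=dropout_time
    )


def simulate_dataset(
    config: GeneratingConfig, rng: np.random.Generator | None = None
) -> SimulatedDataset:
    """Full generation pipeline: Q-matrix, parameters, latents, responses, dropout."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    q_matrix = build_q_matrix(
        config.items_per_time, config.n_attributes, config.n_times, config.anchor_count
    )
    structural = config.structural_parameters()
    items = generate_item_parameters(q_matrix, rng)
    theta = generate_abilities(config.n_persons, structural, rng)
    alpha = generate_attributes(theta, structural, rng)
    responses = generate_responses(alpha, q_matrix, items, rng)
    data = SimulatedDataset(
        responses=responses,
        observed=np.ones(responses.shape, dtype=bool),
        dropout_time=np.full(config.n_persons, config.n_times, dtype=int),
        q_matrix=q_matrix,
        items=items,
        structural=structural,
        theta=theta,
        alpha=alpha,
        config=config,
    )
    if config.attrition_rate > 0:
        data = apply_attrition(data, config.attrition_rate, rng)
    return data


# ---------------------------------------------------------------------------
# plain-text serialization (long-format CSV with NA, per-occasion Q CSVs)


def write_responses_csv(data: SimulatedDataset, path) -> None:
    N, I, T = data.responses.shape
    person, item, time = np.meshgrid(
        np.arange(1, N + 1), np.arange(1, I + 1), np.arange(1, T + 1), indexing="ij"
    )
    resp = data.responses.ravel()
    frame = pd.DataFrame(
        {
            "person": person.ravel(),
            "time": time.ravel(),
            "item": item.ravel(),
            "response": np.where(np.isnan(resp), np.nan, resp).astype(object),
        }
    )
    frame["response"] = frame["response"].map(lambda v: "NA" if pd.isna(v) else int(v))
    frame.to_csv(path, index=False)


def read_responses_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a long-format response CSV; returns (responses, observed)."""
    frame = pd.read_csv(path, na_values=["NA"])
    N = int(frame["person"].max())
    I = int(frame["item"].max())
    T = int(frame["time"].max())
    responses = np.full((N, I, T), np.nan)
    idx = (
        frame["person"].to_numpy() - 1,
        frame["item"].to_numpy() - 1,
        frame["time"].to_numpy() - 1,
    )
    responses[idx] = frame["response"].to_numpy(dtype=float)
    return responses, ~np.isnan(responses)


def write_q_matrix_csv(q_matrix: QMatrix, directory) -> list:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for t in range(q_matrix.n_times):
        frame = pd.DataFrame(
            q_matrix.entries[t],
            index=pd.RangeIndex(1, q_matrix.n_items + 1, name="item"),
            columns=[f"attr{k + 1}" for k in range(q_matrix.n_attributes)],
        )
        path = directory / f"q_matrix_t{t + 1}.csv"
        frame.to_csv(path)
        paths.append(path)
    return paths


def read_q_matrix_csv(paths, anchor_count: int = 0) -> QMatrix:
    entries = np.stack(
        [pd.read_csv(p, index_col="item").to_numpy(dtype=np.int8) for p in paths]
    )
    return QMatrix(entries=entries, anchor_count=anchor_count)


def write_truth_json(data: SimulatedDataset, path) -> None:
    """Structured sidecar with every generating parameter and latent value."""
    truth = {
        "lambda0": data.items.lambda0.tolist(),
        "lambda1": data.items.lambda1.tolist(),
        "xi": data.structural.xi.tolist(),
        "beta": data.structural.beta.tolist(),
        "mu": data.structural.mu.tolist(),
        "sigma": data.structural.sigma.tolist(),
        "theta": data.theta.tolist(),
        "alpha": data.alpha.tolist(),
        "dropout_time": data.dropout_time.tolist(),
        "anchor_count": data.q_matrix.anchor_count,
    }
    Path(path).write_text(json.dumps(truth))
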