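"""Convergence assessment via the potential scale reduction factor (PSRF).

The classic two-or-more-chain Gelman–Rubin construction: with C chains of S
kept draws each, let W be the mean within-chain sample variance and B the
between-chain variance (S times the variance of chain means).  The pooled
posterior-variance estimate is ``V = (S-1)/S * W + B/S`` and

    PSRF = sqrt(V / W).

Values near 1 indicate the chains have mixed; values above ~1.1 (or 1.2 by a
looser convention) flag non-convergence.  The split-chain refinement is
available as an option but off by default.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["psrf", "psrf_table"]


def psrf(chains, split: bool = False) -> float:
    """Potential scale reduction factor for one scalar parameter.

    Parameters
    ----------
    chains
        Array of shape (C, S): C >= 2 chains with S >= 2 kept draws each.
    split
        If true, each chain is split in half first (a stricter variant that
        also detects within-chain drift).

    If every draw is identical (zero within-chain variance) the statistic is
    degenerate; 1.0 is returned with a warning.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need a (C, S) array with at least 2 chains")
    if chains.shape[1] < 2:
        raise ValueError("need at least 2 draws per chain")
    if split:
        half = chains.shape[1] // 2
        chains = np.vstack([chains[:, :half], chains[:, half : 2 * half]])
    S = chains.shape[1]
    within = chains.var(axis=1, ddof=1).mean()
    if within == 0.0:
        warnings.warn("all draws identical; PSRF degenerate, returning 1", stacklevel=2)
        return 1.0
    between = S * chains.mean(axis=1).var(ddof=1)
    pooled = (S - 1) / S * within + between / S
    return float(np.sqrt(pooled / within))


def psrf_table(per_chain_draws: list[dict], include: tuple = None, split: bool = False) -> pd.DataFrame:
    """Per-parameter PSRF table from per-chain draw dictionaries.

    ``per_chain_draws`` is a list (one entry per chain) of dicts mapping a
    parameter-group name to an array whose first axis is the kept iteration.
    Binary latent attributes are not monitored (their within-chain variance
    degenerates); every continuous scalar is.  Returns a tidy frame with
    columns ``group``, ``index``, ``psrf`` and pass flags at the 1.1 and 1.2
    thresholds.
    """
    groups = include if include is not None else tuple(per_chain_draws[0])
    rows = []
    for name in groups:
        stacked = np.stack([np.asarray(d[name], dtype=float) for d in per_chain_draws])
        C, S = stacked.shape[:2]
        flat = stacked.reshape(C, S, -1)
        shape = stacked.shape[2:]
        for j in range(flat.shape[2]):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                value = psrf(flat[:, :, j], split=split)
            rows.append(
                {
                    "group": name,
                    "index": np.unravel_index(j, shape) if shape else (),
                    "psrf": value,
                }
            )
    table = pd.DataFrame(rows)
    table["converged_1.1"] = table["psrf"] < 1.1
    table["converged_1.2"] = table["psrf"] < 1.2
    return table
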