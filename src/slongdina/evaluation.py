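"""Recovery metrics: bias, RMSE, correlation, and classification rates.

Parameter recovery across replications uses, per parameter with true value v
and estimates v_hat_1..v_hat_R:

    bias = mean(v_hat_r - v),    RMSE = sqrt(mean((v_hat_r - v)^2)),

plus the Pearson correlation between true and estimated values where a whole
vector of parameters (e.g. abilities) is compared within a replication.

Attribute recovery uses the attribute correct classification rate (ACCR:
per-attribute agreement), the pattern correct classification rate (PCCR: the
whole K-vector correct at one occasion) and the Longitudinal PCCR (all T*K
attributes correct).  Because the study retains dropped students as latent
cases, every rate comes in two populations:

* ``all`` — every person at every occasion, post-dropout classifications
  coming from the structurally-informed posterior;
* ``observed`` — only person-times actually observed; the longitudinal rate
  is then over students observed at all occasions (completers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "bias",
    "rmse",
    "correlation",
    "accr",
    "pccr",
    "longitudinal_pccr",
    "RecoveryReport",
    "evaluate_fit",
]


def bias(estimates, truth) -> float:
    """Mean estimation error across replications."""
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size == 0:
        raise ValueError("need at least one estimate")
    return float(np.mean(estimates - truth))


def rmse(estimates, truth) -> float:
    """Root mean square error across replications."""
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size == 0:
        raise ValueError("need at least one estimate")
    return float(np.sqrt(np.mean((estimates - truth) ** 2)))


def correlation(estimates, truths) -> float:
    """Pearson correlation between estimated and true values."""
    estimates = np.asarray(estimates, dtype=float).ravel()
    truths = np.asarray(truths, dtype=float).ravel()
    if estimates.size != truths.size:
        raise ValueError("length mismatch")
    if estimates.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(estimates) == 0 or np.std(truths) == 0:
        raise ValueError("correlation undefined: zero variance")
    return float(np.corrcoef(estimates, truths)[0, 1])


def _check_shapes(alpha_hat, alpha_true):
    alpha_hat = np.asarray(alpha_hat)
    alpha_true = np.asarray(alpha_true)
    if alpha_hat.shape != alpha_true.shape or alpha_hat.ndim != 3:
        raise ValueError("alpha arrays must share shape (N, T, K)")
    return alpha_hat, alpha_true


def accr(alpha_hat, alpha_true, k=None, t=None, observed=None) -> float:
    """Attribute correct classification rate.

    ``k``/``t`` (0-based) restrict to one attribute and/or occasion;
    ``observed`` is an optional (N, T) person-time mask restricting the rate
    to observed person-times.
    """
    alpha_hat, alpha_true = _check_shapes(alpha_hat, alpha_true)
    match = alpha_hat == alpha_true
    keep = np.ones(alpha_hat.shape[:2], dtype=bool)
    if observed is not None:
        keep &= np.asarray(observed, dtype=bool)
    if t is not None:
        sel = np.zeros_like(keep)
        sel[:, t] = True
        keep &= sel
    match = match[keep]
    if k is not None:
        match = match[:, k]
    return float(match.mean())


def pccr(alpha_hat, alpha_true, t, observed=None) -> float:
    """Fraction of persons whose whole K-vector at occasion ``t`` is correct."""
    alpha_hat, alpha_true = _check_shapes(alpha_hat, alpha_true)
    ok = (alpha_hat[:, t, :] == alpha_true[:, t, :]).all(axis=1)
    if observed is not None:
        ok = ok[np.asarray(observed, dtype=bool)[:, t]]
    if ok.size == 0:
        raise ValueError("no persons to score at this occasion")
    return float(ok.mean())


def longitudinal_pccr(alpha_hat, alpha_true, observed=None) -> float:
    """Fraction of persons with all T*K attributes correct.

    With ``observed`` given, only completers (observed at every occasion)
    are scored — the population for which the full longitudinal pattern was
    actually measured.
    """
    alpha_hat, alpha_true = _check_shapes(alpha_hat, alpha_true)
    ok = (alpha_hat == alpha_true).all(axis=(1, 2))
    if observed is not None:
        ok = ok[np.asarray(observed, dtype=bool).all(axis=1)]
    if ok.size == 0:
        raise ValueError("no completers to score")
    return float(ok.mean())


@dataclass
class RecoveryReport:
    """Per-replication recovery record for one fitted dataset.

    ``parameter_metrics`` holds within-replication summaries (mean error,
    within-replication RMSE across items/persons, correlations);
    ``estimates``/``truths`` keep the raw per-parameter values so
    across-replication bias/RMSE (the study's definition) can be recomputed
    by the aggregation layer.
    """

    parameter_metrics: pd.DataFrame
    estimates: dict = field(repr=False, default_factory=dict)
    truths: dict = field(repr=False, default_factory=dict)
    accr_all: np.ndarray = None  # (T, K)
    accr_observed: np.ndarray = None
    pccr_all: np.ndarray = None  # (T,)
    pccr_observed: np.ndarray = None
    longitudinal_pccr_all: float = None
    longitudinal_pccr_observed: float = None
    n_completers: int = 0
    median_psrf: float = None

    def to_tidy(self, **keys) -> pd.DataFrame:
        """Tidy metric rows (one per metric/level), tagged with ``keys``."""
        rows = []
        T, K = self.accr_all.shape
        for t in range(T):
            for k in range(K):
                rows.append(("accr_all", f"t{t + 1}k{k + 1}", self.accr_all[t, k]))
                rows.append(("accr_observed", f"t{t + 1}k{k + 1}", self.accr_observed[t, k]))
            rows.append(("pccr_all", f"t{t + 1}", self.pccr_all[t]))
            rows.append(("pccr_observed", f"t{t + 1}", self.pccr_observed[t]))
        rows.append(("longitudinal_pccr_all", "", self.longitudinal_pccr_all))
        rows.append(("longitudinal_pccr_observed", "", self.longitudinal_pccr_observed))
        rows.append(("median_psrf", "", self.median_psrf))
        frame = pd.DataFrame(rows, columns=["metric", "level", "value"])
        for key, val in keys.items():
            frame[key] = val
        return frame


def evaluate_fit(estimator, data) -> RecoveryReport:
    """Score one fitted :class:`~slongdina.SLongDINA` against generating truth."""
    truth_items = data.items
    truth_struct = data.structural
    obs_persons = data.observed_persons()  # (N, T)

    est = {
        "lambda0": estimator.lambda0_.ravel(),
        "lambda1": estimator.lambda1_.ravel(),
        "xi": estimator.xi_,
        "beta": estimator.beta_,
        "mu": estimator.mu_[1:],
        "sigma": estimator.sigma_[np.triu_indices_from(estimator.sigma_)][1:],
        "theta": estimator.theta_,
    }
    tru = {
        "lambda0": truth_items.lambda0.ravel(),
        "lambda1": truth_items.lambda1.ravel(),
        "xi": truth_struct.xi,
        "beta": truth_struct.beta,
        "mu": truth_struct.mu[1:],
        "sigma": truth_struct.sigma[np.triu_indices_from(truth_struct.sigma)][1:],
        "theta": data.theta,
    }

    def safe_cor(a, b):
        # undefined for short or constant-truth classes (e.g. equal slopes)
        try:
            return correlation(a, b)
        except ValueError:
            return np.nan

    rows = []
    for name in ("lambda0", "lambda1", "xi", "beta", "mu", "sigma"):
        err = est[name] - tru[name]
        rows.append(
            {
                "class": name,
                "bias": float(err.mean()),
                "rmse": float(np.sqrt((err**2).mean())),
                "cor": safe_cor(est[name], tru[name]),
            }
        )
    for t in range(data.n_times):  # person parameters, per occasion
        err = est["theta"][:, t] - tru["theta"][:, t]
        rows.append(
            {
                "class": f"theta_t{t + 1}",
                "bias": float(err.mean()),
                "rmse": float(np.sqrt((err**2).mean())),
                "cor": correlation(est["theta"][:, t], tru["theta"][:, t]),
            }
        )

    T, K = data.alpha.shape[1:]
    a_hat, a_true = estimator.alpha_, data.alpha
    report = RecoveryReport(
        parameter_metrics=pd.DataFrame(rows),
        estimates=est,
        truths=tru,
        accr_all=np.array([[accr(a_hat, a_true, k=k, t=t) for k in range(K)] for t in range(T)]),
        accr_observed=np.array(
            [[accr(a_hat, a_true, k=k, t=t, observed=obs_persons) for k in range(K)] for t in range(T)]
        ),
        pccr_all=np.array([pccr(a_hat, a_true, t) for t in range(T)]),
        pccr_observed=np.array([pccr(a_hat, a_true, t, observed=obs_persons) for t in range(T)]),
        longitudinal_pccr_all=longitudinal_pccr(a_hat, a_true),
        longitudinal_pccr_observed=longitudinal_pccr(a_hat, a_true, observed=obs_persons),
        n_completers=int(obs_persons.all(axis=1).sum()),
        median_psrf=estimator.median_psrf(),
    )
    return report
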