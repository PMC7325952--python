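"""Factorial simulation-study orchestration.

The study crosses sample size (200, 400) x per-occasion attrition rate
(0, 5, 10, 20, 40, 60%) x test length (15, 30 items) with T = 3 occasions
and K = 4 attributes, replicated R times per cell.  Each replication:
generate a complete dataset, inject monotone random dropout, fit the model
by MCMC, and score recovery against the generating truth.

Seeding is pure: (master seed, condition, replication) deterministically
derives independent generation and sampling streams, so any cell can be
reproduced bit-exactly regardless of execution order or worker count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .estimator import SLongDINA
from .evaluation import RecoveryReport, evaluate_fit
from .simulate import GeneratingConfig, simulate_dataset

__all__ = [
    "Condition",
    "StudyDesign",
    "full_design",
    "desk_design",
    "replication_seeds",
    "run_replication",
    "run_study",
    "aggregate_records",
]


@dataclass(frozen=True)
class Condition:
    n_persons: int
    items_per_time: int
    attrition_rate: float

    def key(self) -> str:
        return f"N{self.n_persons}_I{self.items_per_time}_M{int(round(self.attrition_rate * 100))}"


@dataclass(frozen=True)
class StudyDesign:
    n_levels: tuple = (200, 400)
    attrition_levels: tuple = (0.0, 0.05, 0.10, 0.20, 0.40, 0.60)
    items_levels: tuple = (15, 30)
    n_times: int = 3
    n_attributes: int = 4
    replications: int = 30
    master_seed: int = 0
    n_chains: int = 2
    n_iter: int = 15000
    burn_in: int = 10000

    def __post_init__(self):
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        if not (self.n_levels and self.attrition_levels and self.items_levels):
            raise ValueError("all factor level lists must be nonempty")

    def conditions(self) -> list[Condition]:
        return [
            Condition(n, i, m)
            for n in self.n_levels
            for m in self.attrition_levels
            for i in self.items_levels
        ]


def full_design(master_seed: int = 0) -> StudyDesign:
    """The full study protocol: R = 30, chains of 15,000 with 10,000 burn-in."""
    return StudyDesign(master_seed=master_seed)


def desk_design(master_seed: int = 0) -> StudyDesign:
    """Scaled-down protocol for desk checks: R = 3, chains of 5,000/2,500."""
    return StudyDesign(replications=3, n_iter=5000, burn_in=2500, master_seed=master_seed)


def replication_seeds(master_seed: int, condition: Condition, replication: int):
    """Deterministic (generation, mcmc) seed pair for one replication."""
    key = (
        condition.n_persons,
        condition.items_per_time,
        int(round(condition.attrition_rate * 1000)),
        replication,
    )
    children = np.random.SeedSequence(master_seed, spawn_key=key).spawn(2)
    return children[0], children[1]


def run_replication(
    condition: Condition,
    replication: int,
    design: StudyDesign,
) -> RecoveryReport:
    """Generate -> drop out -> fit -> evaluate, fully determined by the seeds."""
    gen_seed, mcmc_seed = replication_seeds(design.master_seed, condition, replication)
    config = GeneratingConfig(
        n_persons=condition.n_persons,
        items_per_time=condition.items_per_time,
        n_times=design.n_times,
        n_attributes=design.n_attributes,
        attrition_rate=condition.attrition_rate,
    )
    data = simulate_dataset(config, rng=np.random.default_rng(gen_seed))
    est = SLongDINA(
        n_chains=design.n_chains,
        n_iter=design.n_iter,
        burn_in=design.burn_in,
        random_state=mcmc_seed,
    )
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # non-convergence is recorded via PSRF
        est.fit(data.responses, data.q_matrix)
    return evaluate_fit(est, data)


def run_study(
    design: StudyDesign,
    out_dir=None,
    n_jobs: int = 1,
    conditions: list[Condition] | None = None,
) -> pd.DataFrame:
    """Run all conditions x replications; returns tidy per-replication records.

    With ``out_dir`` given, each replication's record is written to a JSON
    file as it completes and already-completed replications are skipped on
    rerun (resumability).  Failures are recorded and skipped, never fatal.
    """
    if conditions is None:
        conditions = design.conditions()
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    tasks = [(c, r) for c in conditions for r in range(design.replications)]

    def one(cond, rep):
        path = out_dir / f"{cond.key()}_rep{rep}.json" if out_dir is not None else None
        if path is not None and path.exists():
            return json.loads(path.read_text())
        try:
            report = run_replication(cond, rep, design)
            record = _record_from_report(report, cond, rep)
        except Exception as err:  # pragma: no cover - defensive
            record = {"condition": cond.key(), "replication": rep, "failed": str(err)}
        if path is not None:
            path.write_text(json.dumps(record))
        return record

    records = Parallel(n_jobs=n_jobs)(delayed(one)(c, r) for c, r in tasks)
    frames = []
    for rec in records:
        if "failed" in rec:
            frames.append(pd.DataFrame([{"metric": "failed", "level": rec["failed"],
                                         "value": np.nan, **{k: rec[k] for k in ("condition", "replication")}}]))
        else:
            frames.append(pd.DataFrame(rec["rows"]))
    return pd.concat(frames, ignore_index=True)


def _record_from_report(report: RecoveryReport, cond: Condition, rep: int) -> dict:
    tidy = report.to_tidy(
        condition=cond.key(),
        n_persons=cond.n_persons,
        items_per_time=cond.items_per_time,
        attrition_rate=cond.attrition_rate,
        replication=rep,
    )
    param = report.parameter_metrics.copy()
    param_rows = [
        {"metric": f"{row['class']}_{stat}", "level": "", "value": row[stat],
         "condition": cond.key(), "n_persons": cond.n_persons,
         "items_per_time": cond.items_per_time,
         "attrition_rate": cond.attrition_rate, "replication": rep}
        for _, row in param.iterrows()
        for stat in ("bias", "rmse", "cor")
    ]
    rows = tidy.to_dict("records") + param_rows
    return {"condition": cond.key(), "replication": rep, "rows": rows}


def aggregate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Mean of every metric over replications, per condition and level."""
    records = records[records["metric"] != "failed"]
    return (
        records.groupby(["condition", "metric", "level"], as_index=False)
        .agg(value=("value", "mean"), replications=("replication", "nunique"))
    )
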