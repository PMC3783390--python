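"""Replication harness: ensemble statistics over seeded scenario runs.

Runs a scenario ``n_reps`` times with consecutive seeds, aggregates per-phase
means/SDs of total productivity and active counts per society, counts
extinctions, and Shapiro-Wilk-tests the normality of the steady-state
productivity distribution of each surviving replicate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import ScenarioConfig
from .scenarios import SCENARIOS, Trajectory

__all__ = [
    "ReplicateSummary",
    "replicate",
    "aggregate",
    "extinction_count",
    "normality_test",
    "write_summary",
    "read_summary",
]

_FLOAT_FMT = "%.10g"


@dataclass
class ReplicateSummary:
    """Ensemble statistics over replicate trajectories of one scenario config."""

    scenario: str
    phases: np.ndarray
    mean_X: dict  # society -> per-phase mean total productivity
    sd_X: dict
    mean_count: dict
    sd_count: dict
    extinction_counts: dict  # society -> number of replicates ending extinct
    final_samples: list  # per replicate: active occupations' final productivity
    normality: list  # per surviving replicate: (W, p)
    seeds: list
    config: ScenarioConfig
    n_reps: int = 0

    @property
    def societies(self) -> list[str]:
        return list(self.mean_X)

    _COLUMNS = ("phase", "society", "mean_X", "sd_X", "mean_count", "sd_count")

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.societies:
            rows.append(
                pd.DataFrame(
                    {
                        "phase": self.phases,
                        "society": s,
                        "mean_X": self.mean_X[s],
                        "sd_X": self.sd_X[s],
                        "mean_count": self.mean_count[s],
                        "sd_count": self.sd_count[s],
                    }
                )
            )
        if not rows:  # empty summary still round-trips as a header-only CSV
            return pd.DataFrame(columns=list(self._COLUMNS))
        return pd.concat(rows, ignore_index=True)


def extinction_count(trajectories: list[Trajectory], society: str) -> int:
    """Replicates whose final state has no active occupation of that society."""
    if not trajectories:
        raise ValueError("empty trajectory list")
    return sum(t.extinct(society) for t in trajectories)


def normality_test(values) -> tuple[float, float]:
    """Shapiro-Wilk test of a steady-state productivity sample.

    Returns (W, p).  Requires at least 3 distinct-valued observations.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError(f"Shapiro-Wilk needs at least 3 observations, got {v.size}")
    if np.ptp(v) == 0:
        raise ValueError("constant sample: normality test undefined")
    res = stats.shapiro(v)
    return float(res.statistic), float(res.pvalue)


def aggregate(scenario: str, trajectories: list[Trajectory], seeds, cfg) -> ReplicateSummary:
    """Per-phase ensemble moments, extinction counts and normality results.

    Replicates are aligned by phase index (all share ``cfg.n_phases``); the
    aggregation is invariant to the order of the trajectory list.
    """
    if not trajectories:
        raise ValueError("no trajectories to aggregate")
    societies = trajectories[0].societies
    phases = trajectories[0].phases
    mean_X, sd_X, mean_count, sd_count, ext = {}, {}, {}, {}, {}
    for s in societies:
        tot = np.stack([t.totals[s] for t in trajectories])
        cnt = np.stack([t.counts[s] for t in trajectories])
        mean_X[s] = tot.mean(axis=0)
        sd_X[s] = tot.std(axis=0, ddof=0)
        mean_count[s] = cnt.mean(axis=0)
        sd_count[s] = cnt.std(axis=0, ddof=0)
        ext[s] = extinction_count(trajectories, s)
    final_samples, normality = [], []
    for t in trajectories:
        sample = t.final_state.x[t.final_state.active]
        final_samples.append(sample)
        if sample.size >= 3 and np.ptp(sample) > 0:
            normality.append(normality_test(sample))
    return ReplicateSummary(
        scenario=scenario,
        phases=phases,
        mean_X=mean_X,
        sd_X=sd_X,
        mean_count=mean_count,
        sd_count=sd_count,
        extinction_counts=ext,
        final_samples=final_samples,
        normality=normality,
        seeds=list(seeds),
        config=cfg,
        n_reps=len(trajectories),
    )


def replicate(
    scenario: str, cfg: ScenarioConfig, n_reps: int = None, base_seed: int = None
) -> ReplicateSummary:
    """Run ``scenario`` with seeds base_seed, base_seed+1, ... and aggregate."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {sorted(SCENARIOS)}")
    n_reps = cfg.n_reps if n_reps is None else n_reps
    base_seed = cfg.seed if base_seed is None else base_seed
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    runner = SCENARIOS[scenario]
    seeds = [base_seed + i for i in range(n_reps)]
    trajectories = [runner(cfg, s) for s in seeds]
    return aggregate(scenario, trajectories, seeds, cfg)


def run_trajectories(scenario: str, cfg: ScenarioConfig, n_reps: int, base_seed: int):
    """Raw replicate trajectories (same seeding convention as :func:`replicate`)."""
    runner = SCENARIOS[scenario]
    return [runner(cfg, base_seed + i) for i in range(n_reps)]


def _config_dict(cfg: ScenarioConfig) -> dict:
    d = {k: v for k, v in vars(cfg).items() if k != "society"}
    if cfg.society is not None:
        d.update(vars(cfg.society))
    return d


def write_summary(summary: ReplicateSummary, path) -> tuple[Path, Path]:
    """Emit trajectory-statistics CSV and run-metadata JSON into directory ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    csv_path = path / "trajectory_stats.csv"
    json_path = path / "summary.json"
    summary.to_dataframe().to_csv(csv_path, index=False, float_format=_FLOAT_FMT)
    W = [w for w, _ in summary.normality]
    P = [p for _, p in summary.normality]
    meta = {
        "scenario": summary.scenario,
        "n_reps": summary.n_reps,
        "seeds": summary.seeds,
        "config": _config_dict(summary.config),
        "extinction_counts": summary.extinction_counts,
        "normality": {
            "n_tested": len(summary.normality),
            "W_mean": float(np.mean(W)) if W else None,
            "W_sd": float(np.std(W)) if W else None,
            "p_mean": float(np.mean(P)) if P else None,
            "p_sd": float(np.std(P)) if P else None,
        },
    }
    json_path.write_text(json.dumps(meta, indent=2, default=_json_default))
    return csv_path, json_path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_summary(path) -> tuple[pd.DataFrame, dict]:
    """Read back what :func:`write_summary` wrote."""
    path = Path(path)
    df = pd.read_csv(path / "trajectory_stats.csv")
    meta = json.loads((path / "summary.json").read_text())
    return df, meta
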