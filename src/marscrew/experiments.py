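"""Monte Carlo harness, factorial/scenario grids, summaries and calibration.

The headline experiment replays the mission many times per team condition
with independent child seeds and summarizes the final-day crew means of
stress, performance and health as mean / SD / min-max tables.  Child seeds
are derived counter-style from the master seed, so any single run can be
replayed in isolation with ``child_seed(master_seed, i)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import CONDITIONS, ModelParameters, TeamConfiguration
from .mission import run_mission

__all__ = [
    "METRICS",
    "MetricSummary",
    "MonteCarloSummary",
    "child_seed",
    "monte_carlo",
    "run_factorial",
    "run_scenario_grid",
    "summarize_to_csv",
    "calibrate_reference",
    "CalibrationResult",
]

METRICS = ("stress", "performance", "health")


def child_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    """Deterministic, independent per-run seed derived from the master seed."""
    return np.random.SeedSequence(int(master_seed), spawn_key=(int(index),))


@dataclass(frozen=True)
class MetricSummary:
    mean: float
    sd: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if not (self.min <= self.mean <= self.max) or self.sd < 0:
            raise ValueError("inconsistent metric summary")


@dataclass(frozen=True)
class MonteCarloSummary:
    """Cross-run summary of final-day crew means for one team configuration."""

    condition: str
    scenario: str | None
    n_runs: int
    master_seed: int
    metrics: Mapping[str, MetricSummary]
    finals: Mapping[str, np.ndarray] = field(repr=False, default=None)  # type: ignore[assignment]

    def mean(self, metric: str) -> float:
        return self.metrics[metric].mean


def _final_means(team: TeamConfiguration, params: ModelParameters, seed_seq) -> dict[str, float]:
    return run_mission(team, params, seed_seq).final_crew_means()


def monte_carlo(
    team: TeamConfiguration,
    params: ModelParameters,
    n_runs: int,
    master_seed: int,
    progress: Callable[[int], None] | None = None,
) -> MonteCarloSummary:
    """Replicate the mission ``n_runs`` times and summarize final-day crew means."""
    if n_runs < 2:
        raise ValueError("n_runs must be at least 2")
    finals = {m: np.empty(n_runs) for m in METRICS}
    for i in range(n_runs):
        result = _final_means(team, params, child_seed(master_seed, i))
        for m in METRICS:
            finals[m][i] = result[m]
        if progress is not None:
            progress(i)
    metrics = {
        m: MetricSummary(
            mean=float(v.mean()),
            sd=float(v.std(ddof=1)),
            min=float(v.min()),
            max=float(v.max()),
        )
        for m, v in finals.items()
    }
    return MonteCarloSummary(
        condition=team.condition,
        scenario=team.scenario,
        n_runs=n_runs,
        master_seed=int(master_seed),
        metrics=metrics,
        finals=finals,
    )


def run_factorial(
    params: ModelParameters,
    n_runs: int,
    master_seed: int,
    scenario: str | None = None,
    progress: Callable[[str, int], None] | None = None,
) -> dict[str, MonteCarloSummary]:
    """Monte Carlo summaries for all four team-composition conditions.

    Conditions share the parameter set and the master seed; they differ only
    in the team configuration (each condition gets its own child-seed
    stream so crews are sampled independently).
    """
    out: dict[str, MonteCarloSummary] = {}
    for idx, condition in enumerate(CONDITIONS):
        team = TeamConfiguration(condition=condition, scenario=scenario)
        cb = (lambda i, c=condition: progress(c, i)) if progress is not None else None
        out[condition] = monte_carlo(team, params, n_runs, master_seed + idx, progress=cb)
    return out


def run_scenario_grid(
    params: ModelParameters,
    n_runs: int,
    master_seed: int,
    scenarios: Sequence[str] = ("high_C_low_N", "balanced", "high_E_high_A"),
) -> dict[tuple[str, str], MonteCarloSummary]:
    """Summaries for every (scenario, condition) cell of the scenario grid."""
    grid: dict[tuple[str, str], MonteCarloSummary] = {}
    for s_idx, scenario in enumerate(scenarios):
        summaries = run_factorial(params, n_runs, master_seed + 1000 * s_idx, scenario=scenario)
        for condition, summary in summaries.items():
            grid[(scenario, condition)] = summary
    return grid


def summarize_to_csv(summaries: Mapping, path: str | Path) -> pd.DataFrame:
    """Write summary rows (metric, team_type, mean, sd, min, max) as CSV.

    Accepts either a condition->summary mapping or a (scenario, condition)
    grid; returns the written DataFrame.
    """
    rows = []
    for key, summary in summaries.items():
        scenario = summary.scenario
        for metric in METRICS:
            ms = summary.metrics[metric]
            rows.append(
                {
                    "metric": metric,
                    "team_type": summary.condition,
                    "scenario": scenario if scenario is not None else "",
                    "mean": ms.mean,
                    "sd": ms.sd,
                    "min": ms.min,
                    "max": ms.max,
                    "n_runs": summary.n_runs,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


# -- calibration -----------------------------------------------------------

@dataclass
class CalibrationResult:
    """Best-found parameter vector with its residuals and evaluation log."""

    params: ModelParameters
    objective: float
    residuals: dict[tuple[str, str], float]
    log: list[dict]

    def save_log(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.log, indent=2))


def _objective(
    free: Mapping[str, float],
    base: ModelParameters,
    targets: Mapping[tuple[str, str], float],
    n_runs: int,
    master_seed: int,
) -> tuple[float, dict[tuple[str, str], float], dict[str, MonteCarloSummary]]:
    params = base.replace(**dict(free))
    summaries = run_factorial(params, n_runs, master_seed)
    residuals = {
        (metric, condition): summaries[condition].mean(metric) - target
        for (metric, condition), target in targets.items()
    }
    return float(sum(r * r for r in residuals.values())), residuals, summaries


def calibrate_reference(
    targets: Mapping[tuple[str, str], float],
    search_space: Mapping[str, tuple[float, float]],
    budget: int,
    master_seed: int,
    base: ModelParameters | None = None,
    n_runs: int = 200,
) -> CalibrationResult:
    """Fit one shared parameter vector to cross-condition target means.

    ``targets`` maps (metric, condition) to the desired Monte Carlo mean of
    the final-day crew mean; ``search_space`` bounds each free parameter.
    The search is a seeded random search over the box (common random
    numbers across evaluations), always including the base point, and never
    raises on an exhausted budget — the best-found vector is returned with
    its residuals.  Every evaluated vector is recorded in the log.
    """
    if budget < 1:
        raise ValueError("budget must be at least 1")
    base = base if base is not None else ModelParameters()
    names = list(search_space)
    lo = np.array([search_space[n][0] for n in names])
    hi = np.array([search_space[n][1] for n in names])
    rng = np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(0xCA1,)))

    candidates = [{n: float(getattr(base, n)) for n in names}]
    while len(candidates) < budget:
        draw = lo + rng.random(len(names)) * (hi - lo)
        candidates.append(dict(zip(names, draw.astype(float))))

    log: list[dict] = []
    best = None
    for free in candidates:
        value, residuals, _ = _objective(free, base, targets, n_runs, master_seed)
        log.append(
            {
                "free": free,
                "objective": value,
                "n_runs": n_runs,
                "master_seed": master_seed,
            }
        )
        if best is None or value < best[0]:
            best = (value, free, residuals)
    value, free, residuals = best
    return CalibrationResult(
        params=base.replace(**free),
        objective=value,
        residuals=residuals,
        log=log,
    )
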