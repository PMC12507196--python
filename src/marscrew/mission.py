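"""The daily mission scheduler and trajectory recorder.

Each simulated day runs a fixed-order update:

1. task assignment (domain-weighted task list, proficiency-preferential
   with count balancing; workload accrues with overnight decay);
2. stochastic mission events (per-class daily firing, finite duration,
   role-matched attenuation of the environmental-stress surcharge);
3. pairwise social interactions (support/conflict bookkeeping, cohesion
   matrix updates);
4. stress components and the clamped overall stress level — sleep for the
   current day is driven by the *previous* day's stress (sleep precedes the
   workday it restores; day 1 uses the initial stress, giving 8 h);
5. performance (inverted-U curve) and the health update;
6. team cohesion and trajectory recording.

Running the same configuration and seed twice yields bit-identical
trajectories.
"""

from __future__ import annotations

import dataclasses
import json
from math import exp
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import social, stress
from .config import DOMAINS, ModelParameters, TeamConfiguration
from .crew import Agent, build_crew

__all__ = [
    "MissionEvent",
    "Trajectory",
    "assign_tasks",
    "draw_events",
    "event_surcharge",
    "update_health",
    "Mission",
    "run_mission",
    "trajectory_to_frame",
    "write_trajectory",
]

#: Cohesion-matrix snapshots are stored every this many days.
COHESION_SNAPSHOT_INTERVAL = 10

_RECORDED = ("stress", "performance", "health", "sleep_hours", "effective_fatigue",
             "social_support", "conflict", "tasks")


@dataclass
class MissionEvent:
    """An active stochastic mission event adding environmental stress."""

    kind: str
    magnitude: float
    remaining_days: int
    matched_role: str

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("event magnitude must be non-negative")


@dataclass
class Trajectory:
    """Per-day, per-agent records of one mission run plus run metadata."""

    team: TeamConfiguration
    seed: int
    stress: np.ndarray  # (days, agents)
    performance: np.ndarray
    health: np.ndarray
    sleep_hours: np.ndarray
    effective_fatigue: np.ndarray
    social_support: np.ndarray
    conflict: np.ndarray
    tasks: np.ndarray  # integer task counts
    team_cohesion: np.ndarray  # (days,)
    cohesion_snapshots: dict[int, np.ndarray] = field(default_factory=dict)
    params: ModelParameters = field(default_factory=ModelParameters)

    @property
    def n_days(self) -> int:
        return self.stress.shape[0]

    @property
    def n_agents(self) -> int:
        return self.stress.shape[1]

    def final_crew_means(self) -> dict[str, float]:
        """Crew-mean stress, performance and health on the final day."""
        return {
            "stress": float(self.stress[-1].mean()),
            "performance": float(self.performance[-1].mean()),
            "health": float(self.health[-1].mean()),
        }


def assign_tasks(
    day: int,
    crew: list[Agent],
    params: ModelParameters,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Distribute the day's task list; returns (task counts, required hours).

    The crew-total task count is Poisson around ``tasks_per_day_mean`` and
    each task carries a domain drawn from ``task_domain_weights``.  Tasks go
    preferentially to the highest-proficiency agent after a load-balancing
    discount proportional to how far an agent's count leads the least-loaded
    crew member; the preference is softmax-stochastic with temperature
    ``assignment_temperature`` (0 recovers a greedy argmax, with daily
    re-randomized scan order so ties carry no index bias), reflecting that
    real task routing tracks competence only imperfectly.  A task takes
    base_hours / (0.25 + proficiency) hours, so a specialist (0.90) needs
    roughly half the time of a novice (0.30).  Each agent's cumulative
    workload decays overnight and then accrues today's hours.
    """
    n = len(crew)
    total = int(rng.poisson(params.tasks_per_day_mean))
    w = np.asarray(params.task_domain_weights, dtype=float)
    cumw = np.cumsum(w / w.sum())
    domains = np.searchsorted(cumw, rng.random(total)).tolist() if total else []
    order = rng.permutation(n).tolist()
    picks = rng.random(total).tolist() if total else []

    prof = [[crew[i].skills.proficiency[d] for d in DOMAINS] for i in range(n)]
    counts = [0] * n
    hours = [0.0] * n
    pen = params.balance_penalty
    tau = params.assignment_temperature
    base = params.task_base_hours
    for t, d in enumerate(domains):
        mn = min(counts)
        scores = [prof[i][d] - pen * (counts[i] - mn) for i in order]
        if tau > 0:
            top = max(scores)
            weights = [exp((sc - top) / tau) for sc in scores]
            target = picks[t] * sum(weights)
            acc = 0.0
            for pos, wt in enumerate(weights):
                acc += wt
                if target <= acc:
                    break
            best_i = order[pos]
        else:
            best_i = order[scores.index(max(scores))]
        counts[best_i] += 1
        hours[best_i] += base / (0.25 + prof[best_i][d])

    for i, agent in enumerate(crew):
        st = agent.state
        st.cumulative_workload = st.cumulative_workload * (1.0 - params.workload_recovery_rate) + hours[i]
        st.tasks_today = counts[i]
        st.time_required = hours[i]
    return np.asarray(counts, dtype=float), np.asarray(hours, dtype=float)


def draw_events(
    day: int,
    active_events: list[MissionEvent],
    params: ModelParameters,
    rng: np.random.Generator,
) -> list[MissionEvent]:
    """Advance the active-event list by one day and fire new events.

    Carried-over events lose one remaining day (expiring at zero); each
    event class then fires independently with its configured probability,
    entering the list at full duration.
    """
    updated: list[MissionEvent] = []
    for ev in active_events:
        if ev.remaining_days > 1:
            updated.append(dataclasses.replace(ev, remaining_days=ev.remaining_days - 1))
    for kind, spec in params.events:
        if rng.random() < spec.probability:
            updated.append(
                MissionEvent(
                    kind=kind,
                    magnitude=spec.magnitude,
                    remaining_days=spec.duration_days,
                    matched_role=spec.matched_role,
                )
            )
    return updated


def event_surcharge(
    active_events: list[MissionEvent],
    roles_present: frozenset[str] | set[str],
    params: ModelParameters,
) -> float:
    """Total environmental-stress surcharge from active events.

    An event whose matched role is held by any crew member contributes only
    ``role_match_attenuation`` times its magnitude — the specialist absorbs
    part of the disruption for the whole crew.
    """
    total = 0.0
    for ev in active_events:
        factor = params.role_match_attenuation if ev.matched_role in roles_present else 1.0
        total += ev.magnitude * factor
    return total


def update_health(health, s, params: ModelParameters):
    """Stress-gated health dynamics, clamped to [0, 1].

    Health declines in proportion to stress above the threshold theta_H and
    recovers toward 1 (saturating) in proportion to the margin below it; at
    S = theta_H it is unchanged.
    """
    health = np.asarray(health, dtype=float)
    s = np.asarray(s, dtype=float)
    over = np.maximum(0.0, s - params.health_stress_threshold)
    under = np.maximum(0.0, params.health_stress_threshold - s)
    out = health - params.health_decline_rate * over + params.health_recovery_rate * under * (1.0 - health)
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


class Mission:
    """Simulation state for one mission run."""

    def __init__(
        self,
        team: TeamConfiguration,
        params: ModelParameters,
        rng: np.random.Generator,
    ) -> None:
        self.team = team
        self.params = params
        self.rng = rng
        self.crew = build_crew(team, params, rng)
        n = params.crew_size
        self.day = 0
        self.active_events: list[MissionEvent] = []
        self.cohesion = social.initial_cohesion_matrix(n, params.initial_cohesion)
        self.roles_present = frozenset(a.skills.role for a in self.crew)

        # fixed per-agent vectors
        self._pf = np.array([a.pf for a in self.crew])
        self._agree = np.array([a.personality.agreeableness for a in self.crew])
        openness = np.array([a.personality.openness for a in self.crew])
        self._cultural = np.asarray(
            social.cultural_adaptation_factor(openness, team, params.cultural_gamma)
        ) * np.ones(n)

        # mutable state vectors (mirrored onto Agent.state after each step)
        self._s = np.full(n, params.initial_stress)
        self._h = np.full(n, params.initial_health)
        self._p = np.ones(n)

        days = params.mission_days
        self._rec = {m: np.empty((days, n)) for m in _RECORDED}
        self._rec_tc = np.empty(days)
        self.snapshots: dict[int, np.ndarray] = {}

    # -- one day ---------------------------------------------------------
    def step(self) -> None:
        params = self.params
        crew = self.crew
        n = params.crew_size
        rng = self.rng

        # (1) tasking, (2) events
        nt, t_req = assign_tasks(self.day, crew, params, rng)
        self.active_events = draw_events(self.day, self.active_events, params, rng)
        surcharge = event_surcharge(self.active_events, self.roles_present, params)

        # (3) social interactions
        pairs = social.select_partners(n, rng, params.partners_per_agent)
        for pair in pairs:
            a, b = crew[pair[0]], crew[pair[1]]
            positive = social.interaction_outcome(a, b, params, rng)
            social.apply_interaction(a, b, positive, params)
            social.update_cohesion(self.cohesion, pair, positive, params.cohesion_rate)
        ssu = np.array([a.state.social_support for a in crew])
        cl = np.array([a.state.conflict for a in crew])

        # (4) stress components; sleep lags stress by one day
        nt_mean = nt.mean()
        es = stress.event_stress(nt, nt_mean) if nt_mean > 0 else np.zeros(n)
        tp = stress.time_pressure(t_req, params.t_available)
        ss = stress.social_stress(cl, ssu, self._agree, params.cl_max, params.ssu_max)
        ss = np.where(ss > 0, ss * self._cultural, ss)
        envs_crew = stress.environmental_stress(params, rng, surcharge)
        envs = envs_crew * self._cultural
        sh = stress.sleep_hours(self._s)  # previous day's stress
        cw = np.array([a.state.cumulative_workload for a in crew])
        ef = stress.effective_fatigue(sh, cw, params.cw_max)
        raw = (
            params.w_es * es
            + params.w_tp * tp
            + params.w_ef * ef
            + params.w_ss * ss
            + params.w_envs * envs
            + self._pf
        )
        self._s = np.clip(raw, 0.0, 1.0)

        # (5)-(7) performance and health
        self._p = stress.performance(self._s, params.k, params.s_opt)
        self._h = update_health(self._h, self._s, params)

        # (8) team cohesion
        tc = social.team_cohesion(ssu.mean(), cl.mean(), params.ssu_max, params.cl_max)

        # (9) record and mirror state back onto agents
        d = self.day
        rec = self._rec
        rec["stress"][d] = self._s
        rec["performance"][d] = self._p
        rec["health"][d] = self._h
        rec["sleep_hours"][d] = sh
        rec["effective_fatigue"][d] = ef
        rec["social_support"][d] = ssu
        rec["conflict"][d] = cl
        rec["tasks"][d] = nt
        self._rec_tc[d] = tc
        if (d + 1) % COHESION_SNAPSHOT_INTERVAL == 0 or d == params.mission_days - 1:
            self.snapshots[d + 1] = self.cohesion.copy()
        for i, agent in enumerate(crew):
            st = agent.state
            st.stress = float(self._s[i])
            st.performance = float(self._p[i])
            st.health = float(self._h[i])
            st.sleep_hours = float(sh[i])
            st.effective_fatigue = float(ef[i])
        self.day += 1

    def run(self) -> None:
        for _ in range(self.params.mission_days):
            self.step()

    def trajectory(self, seed: int) -> Trajectory:
        rec = self._rec
        return Trajectory(
            team=self.team,
            seed=seed,
            stress=rec["stress"],
            performance=rec["performance"],
            health=rec["health"],
            sleep_hours=rec["sleep_hours"],
            effective_fatigue=rec["effective_fatigue"],
            social_support=rec["social_support"],
            conflict=rec["conflict"],
            tasks=rec["tasks"],
            team_cohesion=self._rec_tc,
            cohesion_snapshots=self.snapshots,
            params=self.params,
        )


def run_mission(
    team: TeamConfiguration,
    params: ModelParameters,
    seed: int | np.random.SeedSequence,
) -> Trajectory:
    """Build a crew and simulate the full mission; returns the Trajectory."""
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
        seed_label = int(ss.generate_state(1)[0] % (2**31))
    else:
        ss = np.random.SeedSequence(int(seed))
        seed_label = int(seed)
    mission = Mission(team, params, np.random.default_rng(ss))
    mission.run()
    return mission.trajectory(seed_label)


# -- export ---------------------------------------------------------------

def trajectory_to_frame(traj: Trajectory, run_id: str = "run0") -> pd.DataFrame:
    """Long-format per-day records: (run_id, day, agent_id, metric, value).

    Team cohesion, a crew-level series, is emitted with agent_id -1.
    """
    days = np.arange(1, traj.n_days + 1)
    frames = []
    for metric in _RECORDED:
        arr = getattr(traj, metric)
        df = pd.DataFrame(arr, columns=[f"{i}" for i in range(traj.n_agents)])
        df.insert(0, "day", days)
        long = df.melt(id_vars="day", var_name="agent_id", value_name="value")
        long["metric"] = metric
        frames.append(long)
    tc = pd.DataFrame(
        {"day": days, "agent_id": "-1", "value": traj.team_cohesion, "metric": "team_cohesion"}
    )
    frames.append(tc)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "run_id", run_id)
    out["agent_id"] = out["agent_id"].astype(int)
    return out[["run_id", "day", "agent_id", "metric", "value"]]


def write_trajectory(traj: Trajectory, path: str | Path, run_id: str = "run0") -> None:
    """Write the long-format CSV plus a JSON metadata sidecar (config echo, seed)."""
    path = Path(path)
    trajectory_to_frame(traj, run_id).to_csv(path, index=False)
    from . import __version__

    meta = {
        "run_id": run_id,
        "seed": traj.seed,
        "condition": traj.team.condition,
        "scenario": traj.team.scenario,
        "mission_days": traj.params.mission_days,
        "crew_size": traj.params.crew_size,
        "package_version": __version__,
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))
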