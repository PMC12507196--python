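"""Crew construction: trait sampling, role assignment, initial agent state.

A crew is a list of :class:`Agent` objects.  Personalities are drawn from
per-trait truncated normals (resample-until-valid on [0, 1]); roles and
skill vectors follow the team configuration: uniform crews share one
generalist vector, differentiated crews cycle through the fixed role
sequence engineer, medic, scientist, pilot, engineer, scientist.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import (
    DIFFERENTIATED_ROLE_SEQUENCE,
    DOMAINS,
    ROLE_SKILL_VECTORS,
    TRAITS,
    UNIFORM_SKILL_VECTOR,
    ModelParameters,
    PersonalityProfile,
    SkillProfile,
    TeamConfiguration,
)
from .stress import personality_factor

__all__ = ["AgentState", "Agent", "sample_trait", "assign_roles", "build_crew"]

_MAX_REJECTION_DRAWS = 10_000


@dataclass
class AgentState:
    """Daily mutable state of one agent.

    Bounded fields stay within their stated bounds after every daily step:
    stress, health in [0, 1]; performance in (0, 1]; sleep hours in [4, 8];
    support in [0, SSU_max]; conflict in [0, CL_max]; fatigue and cumulative
    workload are non-negative and unbounded above.
    """

    stress: float
    performance: float
    health: float
    sleep_hours: float = 8.0
    effective_fatigue: float = 0.0
    cumulative_workload: float = 0.0
    social_support: float = 0.0
    conflict: float = 0.0
    tasks_today: int = 0
    time_required: float = 0.0


@dataclass
class Agent:
    """A crew member: fixed traits and skills plus mutable daily state."""

    agent_id: int
    personality: PersonalityProfile
    skills: SkillProfile
    state: AgentState
    pf: float = field(init=False)

    def __post_init__(self) -> None:
        # Trait-fixed susceptibility, computed once (traits never change).
        self.pf = float(
            personality_factor(self.personality.neuroticism, self.personality.conscientiousness)
        )


def sample_trait(mean: float, sd: float, rng: np.random.Generator) -> float:
    """Draw one trait value from a normal truncated to [0, 1].

    Truncation is by rejection (resample until the draw is in range), so the
    result is exactly the conditional distribution; sd = 0 returns the mean.
    """
    if not 0.0 <= mean <= 1.0:
        raise ValueError(f"trait mean must lie in [0, 1], got {mean!r}")
    if sd < 0:
        raise ValueError(f"trait sd must be non-negative, got {sd!r}")
    if sd == 0:
        return float(mean)
    for _ in range(_MAX_REJECTION_DRAWS):
        draw = rng.normal(mean, sd)
        if 0.0 <= draw <= 1.0:
            return float(draw)
    raise RuntimeError("truncated-normal rejection sampling failed to converge")


def assign_roles(condition_or_config: str | TeamConfiguration, crew_size: int) -> list[SkillProfile]:
    """Role plus skill vector for each crew slot.

    Uniform role mode (conditions A, C): every agent is a generalist
    engineer sharing one vector.  Differentiated mode (B, D): the fixed
    role sequence is tiled across the crew, giving a six-person crew two
    engineers, one medic, two scientists and one pilot.
    """
    if isinstance(condition_or_config, TeamConfiguration):
        config = condition_or_config
    else:
        config = TeamConfiguration(condition=condition_or_config)
    profiles: list[SkillProfile] = []
    for i in range(crew_size):
        if config.role_mode == "uniform":
            role = "engineer"
            vector = UNIFORM_SKILL_VECTOR
        else:
            role = DIFFERENTIATED_ROLE_SEQUENCE[i % len(DIFFERENTIATED_ROLE_SEQUENCE)]
            vector = ROLE_SKILL_VECTORS[role]
        profiles.append(SkillProfile(role=role, proficiency=dict(zip(DOMAINS, vector))))
    return profiles


def build_crew(
    team: TeamConfiguration,
    params: ModelParameters,
    rng: np.random.Generator,
) -> list[Agent]:
    """Build the crew for one mission: sampled personalities, roles, initial state.

    Initial state per agent: stress 0.2, performance 1.0 (stress starts at
    the optimum), health 0.9, social support at half its cap, zero conflict
    and workload.  Deterministic given (team, params, rng state).
    """
    skills = assign_roles(team, params.crew_size)
    crew: list[Agent] = []
    for i in range(params.crew_size):
        traits = {
            t: sample_trait(*team.personality_spec[t], rng=rng) for t in TRAITS
        }
        state = AgentState(
            stress=params.initial_stress,
            performance=1.0,
            health=params.initial_health,
            social_support=params.initial_support_frac * params.ssu_max,
            conflict=0.0,
        )
        crew.append(
            Agent(
                agent_id=i,
                personality=PersonalityProfile(**traits),
                skills=skills[i],
                state=state,
            )
        )
    return crew
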