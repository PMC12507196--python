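"""Daily pairwise interactions, cohesion bookkeeping and cultural adaptation.

Each day every agent, in random order, draws two distinct partners without
replacement; the deduplicated union of unordered pairs is the day's
interaction set (each agent ends up in two to four pairs).  An interaction
is positive with probability

    p = clamp01( base + alpha * mean(A) - beta * mean(N) )

over the pair's agreeableness and neuroticism.  Positive interactions add
social support and decay conflict for both members; negative ones do the
reverse.  A symmetric pairwise cohesion matrix tracks tie strength with a
bounded EMA, and team cohesion is the clamped gap between crew-average
support and crew-average conflict.
"""

from __future__ import annotations

import numpy as np

from .config import ModelParameters, TeamConfiguration
from .crew import Agent

__all__ = [
    "select_partners",
    "interaction_probability",
    "interaction_outcome",
    "apply_interaction",
    "update_cohesion",
    "agent_cohesion",
    "team_cohesion",
    "cultural_adaptation_factor",
    "initial_cohesion_matrix",
]


def select_partners(n_agents: int, rng: np.random.Generator, partners_per_agent: int = 2):
    """The day's deduplicated set of unordered interacting pairs.

    Requires at least three agents so that two distinct partners exist.
    """
    if n_agents < 3:
        raise ValueError("partner selection requires a crew of at least 3")
    if partners_per_agent > n_agents - 1:
        raise ValueError("partners_per_agent cannot exceed crew size - 1")
    order = rng.permutation(n_agents).tolist()
    pairs: set[tuple[int, int]] = set()
    for i in order:
        chosen: set[int] = set()
        while len(chosen) < partners_per_agent:
            j = int(rng.integers(n_agents - 1))
            if j >= i:
                j += 1  # skip self
            chosen.add(j)
        for j in chosen:
            pairs.add((i, j) if i < j else (j, i))
    return sorted(pairs)


def interaction_probability(agent_a: Agent, agent_b: Agent, params: ModelParameters) -> float:
    """Closed-form probability that a pair's interaction is positive."""
    mean_a = 0.5 * (agent_a.personality.agreeableness + agent_b.personality.agreeableness)
    mean_n = 0.5 * (agent_a.personality.neuroticism + agent_b.personality.neuroticism)
    p = (
        params.interaction_base_rate
        + params.agreeableness_gain * mean_a
        - params.neuroticism_penalty * mean_n
    )
    return float(np.clip(p, 0.0, 1.0))


def interaction_outcome(
    agent_a: Agent,
    agent_b: Agent,
    params: ModelParameters,
    rng: np.random.Generator,
) -> bool:
    """Bernoulli draw of the pair's outcome; True = positive."""
    return bool(rng.random() < interaction_probability(agent_a, agent_b, params))


def apply_interaction(agent_a: Agent, agent_b: Agent, positive: bool, params: ModelParameters) -> None:
    """Update both members' support and conflict identically.

    Positive: support += delta_s, conflict decays.  Negative: conflict +=
    delta_c, support decays.  Both quantities are then clamped to their caps.
    """
    for agent in (agent_a, agent_b):
        st = agent.state
        if positive:
            st.social_support += params.support_increment
            st.conflict *= 1.0 - params.conflict_decay
        else:
            st.conflict += params.conflict_increment
            st.social_support *= 1.0 - params.support_decay
        st.social_support = min(max(st.social_support, 0.0), params.ssu_max)
        st.conflict = min(max(st.conflict, 0.0), params.cl_max)


def initial_cohesion_matrix(n_agents: int, initial: float) -> np.ndarray:
    """Symmetric tie-strength matrix with every off-diagonal entry at `initial`."""
    m = np.full((n_agents, n_agents), float(initial))
    np.fill_diagonal(m, 0.0)  # diagonal unused
    return m


def update_cohesion(matrix: np.ndarray, pair: tuple[int, int], positive: bool, rate: float) -> None:
    """Bounded EMA on the pair's mutual tie: grow toward 1 on a positive
    interaction, shrink toward 0 on a negative one.  Symmetry preserved."""
    if not 0.0 < rate < 1.0:
        raise ValueError("cohesion rate must lie in (0, 1)")
    i, j = pair
    entry = matrix[i, j]
    entry = entry + rate * (1.0 - entry) if positive else entry * (1.0 - rate)
    matrix[i, j] = matrix[j, i] = entry


def agent_cohesion(matrix: np.ndarray, i: int) -> float:
    """Agent i's average pairwise cohesion with the rest of the team."""
    n = matrix.shape[0]
    if not 0 <= i < n:
        raise IndexError(f"agent index {i} out of range for crew of {n}")
    mask = np.ones(n, dtype=bool)
    mask[i] = False
    return float(matrix[i, mask].mean())


def team_cohesion(ssu_mean: float, cl_mean: float, ssu_max: float = 1.0, cl_max: float = 1.0) -> float:
    """TC = clamp01(SSU_mean/SSU_max - CL_mean/CL_max).

    With unit caps (the reference set) this is exactly the support-minus-
    conflict balance on [0, 1].
    """
    if ssu_max <= 0 or cl_max <= 0:
        raise ValueError("ssu_max and cl_max must be strictly positive")
    return float(np.clip(ssu_mean / ssu_max - cl_mean / cl_max, 0.0, 1.0))


def cultural_adaptation_factor(openness, team: TeamConfiguration | str, gamma: float):
    """Openness-based stress attenuation, active only in personality-
    heterogeneous crews (conditions C, D).

    Returns the multiplier (1 - gamma * openness) applied to an agent's
    environmental stress and to the positive part of their social stress;
    homogeneous crews get 1 (no cultural gap is modeled there).
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    openness = np.asarray(openness, dtype=float)
    if np.any(openness < 0) or np.any(openness > 1):
        raise ValueError("openness must lie in [0, 1]")
    if isinstance(team, TeamConfiguration):
        hetero = team.heterogeneous_personality
    else:
        hetero = team in ("C", "D")
    if not hetero:
        return np.ones_like(openness) if openness.ndim else 1.0
    out = 1.0 - gamma * openness
    return out if openness.ndim else float(out)
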