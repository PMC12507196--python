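"""Domain types, parameter registry, presets and config-file I/O.

The simulator is fully specified by three objects:

* :class:`TeamConfiguration` — which cell of the 2x2 team-composition
  factorial to build (personality heterogeneity x role heterogeneity),
  optionally overlaid with a named personality scenario.
* :class:`ModelParameters` — every weight, rate, cap and probability the
  daily model uses.  Nothing numeric is hard-coded in the engine modules;
  the frozen reference calibration lives in :func:`reference_parameters`.
* a seed.

Configs round-trip through a small YAML dialect (see :func:`load_config`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "TRAITS",
    "DOMAINS",
    "ROLES",
    "CONDITIONS",
    "PersonalityProfile",
    "SkillProfile",
    "EventClass",
    "ModelParameters",
    "TeamConfiguration",
    "ConfigError",
    "scenario_preset",
    "reference_parameters",
    "load_config",
    "save_config",
]

#: Big Five trait names, in canonical order.
TRAITS = ("openness", "conscientiousness", "extraversion", "agreeableness", "neuroticism")

#: Operational task domains, in the order used by skill vectors.
DOMAINS = ("engineering", "medical", "science", "piloting")

#: Crew roles; each role maps onto one task domain.
ROLES = ("engineer", "medic", "scientist", "pilot")

ROLE_DOMAIN = {
    "engineer": "engineering",
    "medic": "medical",
    "scientist": "science",
    "pilot": "piloting",
}

#: The four factorial cells: A homo-skill+personality, B hetero-skill,
#: C hetero-personality, D hetero-skill+personality.
CONDITIONS = ("A", "B", "C", "D")

_DIFFERENTIATED = {"B": True, "D": True, "A": False, "C": False}
_HETERO_PERSONALITY = {"C": True, "D": True, "A": False, "B": False}

# Trait sampling means for the baseline astronaut profile and the per-trait
# sampling SDs of the homogeneous / heterogeneous compositions.
BASE_TRAIT_MEANS = {
    "openness": 0.5,
    "conscientiousness": 0.8,
    "extraversion": 0.5,
    "agreeableness": 0.7,
    "neuroticism": 0.3,
}
HOMOGENEOUS_SD = {t: 0.05 for t in TRAITS}
HETEROGENEOUS_SD = {
    "openness": 0.2,
    "conscientiousness": 0.1,
    "extraversion": 0.2,
    "agreeableness": 0.1,
    "neuroticism": 0.1,
}

# Named personality scenarios: per-trait (low, high) sampling ranges.
_SCENARIOS = {
    "high_C_low_N": {
        "conscientiousness": (0.8, 0.9),
        "neuroticism": (0.1, 0.3),
        "openness": (0.6, 0.7),
        "agreeableness": (0.5, 0.7),
        "extraversion": (0.5, 0.7),
    },
    "balanced": {t: (0.4, 0.6) for t in TRAITS},
    "high_E_high_A": {
        "extraversion": (0.8, 0.9),
        "agreeableness": (0.8, 0.9),
        "openness": (0.5, 0.7),
        "conscientiousness": (0.4, 0.6),
        "neuroticism": (0.4, 0.6),
    },
}

# Skill vectors over DOMAINS.  The uniform crew shares a generalist
# engineer-type vector; the differentiated crew carries one specialist
# vector per role.
UNIFORM_SKILL_VECTOR = (0.85, 0.30, 0.40, 0.30)
ROLE_SKILL_VECTORS = {
    "engineer": (0.90, 0.20, 0.40, 0.35),
    "medic": (0.30, 0.85, 0.35, 0.30),
    "scientist": (0.40, 0.30, 0.90, 0.35),
    "pilot": (0.30, 0.30, 0.30, 0.90),
}

#: Role sequence used to fill a differentiated six-person crew.
DIFFERENTIATED_ROLE_SEQUENCE = ("engineer", "medic", "scientist", "pilot", "engineer", "scientist")


class ConfigError(ValueError):
    """Raised on invalid configuration input; the message names the field."""


def _check_unit(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigError(f"{name} must lie in [0, 1], got {value!r}")


def _check_positive(name: str, value: float) -> None:
    if not value > 0.0:
        raise ConfigError(f"{name} must be strictly positive, got {value!r}")


def _check_nonnegative(name: str, value: float) -> None:
    if value < 0.0:
        raise ConfigError(f"{name} must be non-negative, got {value!r}")


@dataclass(frozen=True)
class PersonalityProfile:
    """An agent's Big Five trait values, each dimensionless on [0, 1]."""

    openness: float
    conscientiousness: float
    extraversion: float
    agreeableness: float
    neuroticism: float

    def __post_init__(self) -> None:
        for t in TRAITS:
            _check_unit(f"personality.{t}", getattr(self, t))

    def as_dict(self) -> dict[str, float]:
        return {t: getattr(self, t) for t in TRAITS}


@dataclass(frozen=True)
class SkillProfile:
    """A role label plus a proficiency vector over the four task domains."""

    role: str
    proficiency: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ConfigError(f"skill.role must be one of {ROLES}, got {self.role!r}")
        if set(self.proficiency) != set(DOMAINS):
            raise ConfigError(
                f"skill.proficiency must cover exactly the domains {DOMAINS}, "
                f"got {sorted(self.proficiency)}"
            )
        for d, v in self.proficiency.items():
            _check_unit(f"skill.proficiency[{d}]", v)

    def vector(self) -> tuple[float, ...]:
        return tuple(self.proficiency[d] for d in DOMAINS)


@dataclass(frozen=True)
class EventClass:
    """One class of stochastic mission event (equipment failure, ...)."""

    probability: float  # per-day firing probability
    magnitude: float  # additive environmental-stress surcharge while active
    duration_days: int
    matched_role: str  # crews holding this role attenuate the surcharge

    def __post_init__(self) -> None:
        _check_unit("event.probability", self.probability)
        _check_nonnegative("event.magnitude", self.magnitude)
        if self.duration_days < 1:
            raise ConfigError(f"event.duration_days must be >= 1, got {self.duration_days}")
        if self.matched_role not in ROLES:
            raise ConfigError(f"event.matched_role must be one of {ROLES}")


@dataclass(frozen=True)
class ModelParameters:
    """Every numeric constant the daily model uses.

    Stress-component weights must sum to 1 (the personality factor enters
    the overall-stress sum unweighted).  All fields carry the frozen
    reference calibration as defaults; see :func:`reference_parameters`.
    """

    # overall-stress component weights (sum to 1)
    w_es: float = 0.20
    w_tp: float = 0.15
    w_ef: float = 0.25
    w_ss: float = 0.20
    w_envs: float = 0.20

    # environmental stress (dimensionless stress units)
    envs_base: float = 2.50
    envs_fluct_sd: float = 0.10

    # stress -> performance (inverted-U)
    k: float = 2.30  # sensitivity of performance to stress deviation
    s_opt: float = 0.2  # optimal stress level

    # normalizers
    cl_max: float = 1.0
    ssu_max: float = 1.0
    cw_max: float = 150.0  # hours of accumulated workload at full fatigue
    t_available: float = 8.0  # working hours per day

    # pairwise interactions
    interaction_base_rate: float = 0.5  # baseline positive-outcome probability
    agreeableness_gain: float = 0.4  # alpha
    neuroticism_penalty: float = 0.4  # beta
    support_increment: float = 0.04  # delta_s, per positive interaction
    conflict_increment: float = 0.05  # delta_c, per negative interaction
    support_decay: float = 0.10  # SSU shrinkage per negative interaction
    conflict_decay: float = 0.10  # CL shrinkage per positive interaction
    partners_per_agent: int = 2

    # stochastic mission events
    events: tuple[tuple[str, EventClass], ...] = (
        ("equipment_failure", EventClass(0.020, 0.50, 5, "engineer")),
        ("comm_delay", EventClass(0.020, 0.30, 3, "pilot")),
        ("environmental_hazard", EventClass(0.010, 0.60, 4, "scientist")),
        ("health_incident", EventClass(0.015, 0.40, 3, "medic")),
    )
    role_match_attenuation: float = 0.5  # surcharge multiplier when role present

    # health dynamics
    health_decline_rate: float = 0.0025  # eta_d
    health_recovery_rate: float = 0.01  # eta_r
    health_stress_threshold: float = 0.45  # theta_H

    # cohesion and cultural adaptation
    cohesion_rate: float = 0.02  # lambda, EMA update per interaction
    initial_cohesion: float = 0.7
    cultural_gamma: float = 0.32  # openness-based stress attenuation (hetero only)

    # daily tasking
    tasks_per_day_mean: float = 24.0  # Poisson mean, crew total
    task_base_hours: float = 1.0
    task_domain_weights: tuple[float, float, float, float] = (0.55, 0.15, 0.15, 0.15)
    balance_penalty: float = 0.3  # proficiency discount per task of lead over min load
    assignment_temperature: float = 0.8  # softmax temperature of the routing preference (0 = greedy)
    workload_recovery_rate: float = 0.05  # overnight CW decay

    # mission shape and initial state
    mission_days: int = 500
    crew_size: int = 6
    initial_stress: float = 0.2
    initial_health: float = 0.9
    initial_support_frac: float = 0.5  # SSU_0 = frac * ssu_max

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        weights = (self.w_es, self.w_tp, self.w_ef, self.w_ss, self.w_envs)
        for name, w in zip(("w_es", "w_tp", "w_ef", "w_ss", "w_envs"), weights):
            _check_nonnegative(name, w)
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ConfigError(
                "stress weights (w_es, w_tp, w_ef, w_ss, w_envs) must sum to 1, "
                f"got {sum(weights)!r}"
            )
        _check_nonnegative("envs_base", self.envs_base)
        _check_nonnegative("envs_fluct_sd", self.envs_fluct_sd)
        _check_positive("k", self.k)
        _check_unit("s_opt", self.s_opt)
        for name in ("cl_max", "ssu_max", "cw_max", "t_available", "task_base_hours"):
            _check_positive(name, getattr(self, name))
        for name in (
            "interaction_base_rate",
            "support_decay",
            "conflict_decay",
            "role_match_attenuation",
            "health_stress_threshold",
            "initial_cohesion",
            "cultural_gamma",
            "initial_stress",
            "initial_health",
            "initial_support_frac",
        ):
            _check_unit(name, getattr(self, name))
        for name in (
            "agreeableness_gain",
            "neuroticism_penalty",
            "support_increment",
            "conflict_increment",
            "health_decline_rate",
            "health_recovery_rate",
            "tasks_per_day_mean",
            "balance_penalty",
            "assignment_temperature",
        ):
            _check_nonnegative(name, getattr(self, name))
        if not 0.0 < self.cohesion_rate < 1.0:
            raise ConfigError(f"cohesion_rate must lie in (0, 1), got {self.cohesion_rate!r}")
        _check_unit("workload_recovery_rate", self.workload_recovery_rate)
        if self.partners_per_agent < 1:
            raise ConfigError("partners_per_agent must be >= 1")
        if self.mission_days < 1:
            raise ConfigError("mission_days must be >= 1")
        if self.crew_size < 3:
            raise ConfigError("crew_size must be >= 3 (pairwise interactions need partners)")
        if len(self.task_domain_weights) != len(DOMAINS):
            raise ConfigError("task_domain_weights must have one weight per domain")
        for w in self.task_domain_weights:
            _check_nonnegative("task_domain_weights", w)
        if sum(self.task_domain_weights) <= 0:
            raise ConfigError("task_domain_weights must not all be zero")
        names = [n for n, _ in self.events]
        if len(names) != len(set(names)):
            raise ConfigError("event class names must be unique")

    # -- convenience ---------------------------------------------------
    @property
    def weights(self) -> tuple[float, float, float, float, float]:
        """(w_es, w_tp, w_ef, w_ss, w_envs)."""
        return (self.w_es, self.w_tp, self.w_ef, self.w_ss, self.w_envs)

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def event_dict(self) -> dict[str, EventClass]:
        return dict(self.events)


def reference_parameters() -> ModelParameters:
    """Return the frozen reference parameter vector.

    This is the single calibrated parameter set used by every reported
    experiment; all constants are the dataclass defaults above.  Calling it
    twice returns equal objects.
    """
    return ModelParameters()


def scenario_preset(name: str) -> dict[str, tuple[float, float]]:
    """Per-trait (low, high) sampling ranges for a named personality scenario."""
    try:
        return dict(_SCENARIOS[name])
    except KeyError:
        raise ConfigError(
            f"unknown scenario {name!r}; expected one of {sorted(_SCENARIOS)}"
        ) from None


@dataclass(frozen=True)
class TeamConfiguration:
    """One cell of the team-composition factorial.

    ``condition`` selects the factorial cell (A/B/C/D); ``scenario``
    optionally overlays a named trait-range preset whose midpoints replace
    the baseline trait means.  ``personality_spec`` maps each trait to its
    sampling (mean, sd); ``role_mode`` is forced by the condition
    (uniform for A/C, differentiated for B/D).
    """

    condition: str
    scenario: str | None = None
    personality_spec: Mapping[str, tuple[float, float]] = field(default=None)  # type: ignore[assignment]
    role_mode: str = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ConfigError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        expected_mode = "differentiated" if _DIFFERENTIATED[self.condition] else "uniform"
        if self.role_mode is None:
            object.__setattr__(self, "role_mode", expected_mode)
        elif self.role_mode != expected_mode:
            raise ConfigError(
                f"condition {self.condition} implies role_mode {expected_mode!r}, "
                f"got {self.role_mode!r}"
            )
        if self.personality_spec is None:
            object.__setattr__(self, "personality_spec", self._default_spec())
        spec = dict(self.personality_spec)
        if set(spec) != set(TRAITS):
            raise ConfigError("personality_spec must cover exactly the Big Five traits")
        for t, (mean, sd) in spec.items():
            _check_unit(f"personality_spec[{t}].mean", mean)
            _check_nonnegative(f"personality_spec[{t}].sd", sd)
        object.__setattr__(self, "personality_spec", spec)

    def _default_spec(self) -> dict[str, tuple[float, float]]:
        if self.scenario is not None:
            ranges = scenario_preset(self.scenario)
            means = {t: (lo + hi) / 2.0 for t, (lo, hi) in ranges.items()}
        else:
            means = dict(BASE_TRAIT_MEANS)
        sds = HETEROGENEOUS_SD if _HETERO_PERSONALITY[self.condition] else HOMOGENEOUS_SD
        return {t: (means[t], sds[t]) for t in TRAITS}

    @property
    def heterogeneous_personality(self) -> bool:
        return _HETERO_PERSONALITY[self.condition]


# ---------------------------------------------------------------------------
# Config-file I/O.  Dialect: a YAML mapping with keys
#   seed: int (required)
#   team: {condition: A|B|C|D, scenario: optional name}
#   parameters: flat ModelParameters field overrides; events as
#     {name: {probability, magnitude, duration_days, matched_role}}
# ---------------------------------------------------------------------------

def _parameters_from_mapping(raw: Mapping) -> ModelParameters:
    raw = dict(raw)
    kwargs: dict = {}
    if "events" in raw:
        ev = raw.pop("events")
        kwargs["events"] = tuple(
            (name, EventClass(**spec)) for name, spec in ev.items()
        )
    if "task_domain_weights" in raw:
        raw["task_domain_weights"] = tuple(raw["task_domain_weights"])
    valid = {f.name for f in dataclasses.fields(ModelParameters)}
    for key, value in raw.items():
        if key not in valid:
            raise ConfigError(f"unknown parameter {key!r}")
        kwargs[key] = value
    return ModelParameters(**kwargs)


def load_config(path: str | Path) -> tuple[TeamConfiguration, ModelParameters, int]:
    """Load and validate a simulation config file.

    Every field except ``seed`` is optional; missing parameters fall back to
    the frozen reference defaults.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    if "seed" not in raw:
        raise ConfigError("config must state an explicit integer 'seed'")
    seed = raw["seed"]
    if not isinstance(seed, int) or isinstance(seed, bool):
        raise ConfigError(f"seed must be an integer, got {seed!r}")
    team_raw = dict(raw.get("team") or {})
    team = TeamConfiguration(
        condition=team_raw.pop("condition", "A"),
        scenario=team_raw.pop("scenario", None),
    )
    if team_raw:
        raise ConfigError(f"unknown team keys: {sorted(team_raw)}")
    params = _parameters_from_mapping(raw.get("parameters") or {})
    return team, params, seed


def save_config(
    path: str | Path,
    team: TeamConfiguration,
    params: ModelParameters,
    seed: int,
) -> None:
    """Write a config file that :func:`load_config` round-trips exactly."""
    payload: dict = {"seed": int(seed), "team": {"condition": team.condition}}
    if team.scenario is not None:
        payload["team"]["scenario"] = team.scenario
    ref = ModelParameters()
    overrides: dict = {}
    for f in dataclasses.fields(ModelParameters):
        value = getattr(params, f.name)
        if value == getattr(ref, f.name):
            continue
        if f.name == "events":
            overrides["events"] = {
                name: dataclasses.asdict(ev) for name, ev in value
            }
        elif f.name == "task_domain_weights":
            overrides[f.name] = list(value)
        else:
            overrides[f.name] = value
    if overrides:
        payload["parameters"] = overrides
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
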