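"""Pure, stateless daily stress and performance equations.

All functions accept scalars or numpy arrays (broadcasting) and carry no
state; randomness enters only through an explicit generator.  The model:

* a fixed personality factor PF = N - 0.5 C (trait-driven susceptibility);
* four daily stress components — task-demand stress ES, time pressure TP,
  social stress SS, environmental stress EnvS — plus effective fatigue EF
  built from stress-curtailed sleep and accumulated workload;
* an overall stress level S as the weighted sum of the components plus PF,
  clamped to [0, 1];
* an inverted-U stress-performance curve P = exp(-k (S - S_opt)^2), which
  peaks at 1 exactly at the optimal stress level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ModelParameters

__all__ = [
    "StressComponents",
    "personality_factor",
    "event_stress",
    "time_pressure",
    "social_stress",
    "environmental_stress",
    "sleep_hours",
    "effective_fatigue",
    "overall_stress",
    "performance",
]


@dataclass(frozen=True)
class StressComponents:
    """Daily stress contributions for one agent (SS and PF may be negative)."""

    pf: float
    es: float
    tp: float
    ss: float
    envs: float
    ef: float

    def __post_init__(self) -> None:
        for name in ("es", "tp", "envs", "ef"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"stress component {name} must be non-negative")


def _check_range(name, value, lo, hi):
    value = np.asarray(value, dtype=float)
    if np.any(value < lo) or np.any(value > hi):
        raise ValueError(f"{name} must lie in [{lo}, {hi}]")
    return value


def personality_factor(neuroticism, conscientiousness):
    """PF = N - 0.5 C; trait-fixed stress susceptibility on [-0.5, 1]."""
    n = _check_range("neuroticism", neuroticism, 0.0, 1.0)
    c = _check_range("conscientiousness", conscientiousness, 0.0, 1.0)
    return n - 0.5 * c


def event_stress(nt_i, nt_mean):
    """ES = NT_i / mean(NT); 0 on a crew-wide no-task day (NT_mean = 0)."""
    nt_i = np.asarray(nt_i, dtype=float)
    if np.any(nt_i < 0):
        raise ValueError("task counts must be non-negative")
    if nt_mean < 0:
        raise ValueError("mean task count must be non-negative")
    if nt_mean == 0:
        return np.zeros_like(nt_i) if nt_i.ndim else 0.0
    return nt_i / nt_mean


def time_pressure(t_required, t_available):
    """TP = T_required / T_available; unbounded above (overload days exceed 1)."""
    if t_available <= 0:
        raise ValueError("t_available must be strictly positive")
    t_required = np.asarray(t_required, dtype=float)
    if np.any(t_required < 0):
        raise ValueError("t_required must be non-negative")
    return t_required / t_available


def social_stress(cl, ssu, agreeableness, cl_max, ssu_max):
    """SS = (CL/CL_max)(1 - A) - (SSU/SSU_max) A, on [-1, 1].

    Conflict loads stress in proportion to disagreeableness; social support
    relieves it in proportion to agreeableness.
    """
    if cl_max <= 0 or ssu_max <= 0:
        raise ValueError("cl_max and ssu_max must be strictly positive")
    cl = _check_range("cl", cl, 0.0, cl_max)
    ssu = _check_range("ssu", ssu, 0.0, ssu_max)
    a = _check_range("agreeableness", agreeableness, 0.0, 1.0)
    return (cl / cl_max) * (1.0 - a) - (ssu / ssu_max) * a


def environmental_stress(
    params: ModelParameters,
    rng: np.random.Generator,
    event_surcharge: float = 0.0,
) -> float:
    """Baseline habitat stress: constant plus a small Gaussian fluctuation.

    The fluctuating baseline is floored at 0; any active mission-event
    surcharge is added on top.
    """
    base = params.envs_base
    if params.envs_fluct_sd > 0:
        base = base + rng.normal(0.0, params.envs_fluct_sd)
    return max(0.0, base) + event_surcharge


def sleep_hours(s):
    """SH = clamp(8 - 2 (S - 0.2), 4, 8): stress curtails sleep below the 8 h baseline."""
    s = _check_range("stress", s, 0.0, 1.0)
    return np.minimum(8.0, np.maximum(4.0, 8.0 - 2.0 * (s - 0.2)))


def effective_fatigue(sh, cw, cw_max):
    """EF = (8 - SH)/8 + CW/CW_max (sleep-debt fraction plus workload backlog).

    Not clamped here; boundedness is enforced only at the overall-stress clamp.
    """
    if cw_max <= 0:
        raise ValueError("cw_max must be strictly positive")
    sh = _check_range("sleep hours", sh, 4.0, 8.0)
    cw = np.asarray(cw, dtype=float)
    if np.any(cw < 0):
        raise ValueError("cumulative workload must be non-negative")
    return (8.0 - sh) / 8.0 + cw / cw_max


def overall_stress(components: StressComponents, weights) -> float:
    """Weighted component sum plus the unweighted personality factor, clamped to [0, 1]."""
    w = np.asarray(weights, dtype=float)
    if w.shape[-1] != 5 or np.any(w < 0) or abs(float(w.sum(axis=-1)) - 1.0) > 1e-9:
        raise ValueError("weights must be 5 non-negative values summing to 1")
    w_es, w_tp, w_ef, w_ss, w_envs = (w[..., i] for i in range(5))
    raw = (
        w_es * np.asarray(components.es)
        + w_tp * np.asarray(components.tp)
        + w_ef * np.asarray(components.ef)
        + w_ss * np.asarray(components.ss)
        + w_envs * np.asarray(components.envs)
        + np.asarray(components.pf)
    )
    return np.clip(raw, 0.0, 1.0)


def performance(s, k, s_opt):
    """Inverted-U stress-performance curve P = exp(-k (S - S_opt)^2), on (0, 1]."""
    if k <= 0:
        raise ValueError("k must be strictly positive")
    _check_range("s_opt", s_opt, 0.0, 1.0)
    s = _check_range("stress", s, 0.0, 1.0)
    return np.exp(-k * (s - s_opt) ** 2)
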