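import numpy as np
import pytest

from marscrew import ModelParameters, TeamConfiguration, reference_parameters


@pytest.fixture
def params() -> ModelParameters:
    return reference_parameters()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(params=["A", "B", "C", "D"])
def condition(request) -> str:
    return request.param


@pytest.fixture
def team(condition) -> TeamConfiguration:
    return TeamConfiguration(condition=condition)


@pytest.fixture
def short_params(params) -> ModelParameters:
    """Reference parameters on a short mission, for fast end-to-end runs."""
    return params.replace(mission_days=40)


@pytest.fixture
def quiet_params(params) -> ModelParameters:
    """All stochastic elements disabled: no events, no tasks, no
    environmental fluctuation, interactions forced positive."""
    return params.replace(
        mission_days=30,
        tasks_per_day_mean=0.0,
        envs_fluct_sd=0.0,
        events=tuple((k, e.__class__(0.0, e.magnitude, e.duration_days, e.matched_role))
                     for k, e in params.events),
        interaction_base_rate=1.0,
        agreeableness_gain=0.0,
        neuroticism_penalty=0.0,
        # partner draws reach agents unevenly on a given day, so interaction
        # effects must be neutral for exact cross-agent symmetry
        support_increment=0.0,
        conflict_increment=0.0,
        support_decay=0.0,
        conflict_decay=0.0,
    )
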