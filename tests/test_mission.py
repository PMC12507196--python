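"""Daily scheduler: tasking, events, health, the full feedback loop."""

import numpy as np
import pytest

from marscrew import TeamConfiguration, build_crew, run_mission
from marscrew.mission import (
    MissionEvent,
    assign_tasks,
    draw_events,
    event_surcharge,
    trajectory_to_frame,
    update_health,
    write_trajectory,
)


class TestAssignTasks:
    def test_task_duration_scales_with_proficiency(self):
        # specialist vs novice on a one-hour engineering task
        assert 1.0 / (0.25 + 0.90) == pytest.approx(0.8696, abs=1e-4)
        assert 1.0 / (0.25 + 0.30) == pytest.approx(1.8182, abs=1e-4)

    def test_uniform_crew_expected_share_is_equal(self, params, rng):
        crew = build_crew(TeamConfiguration("A"), params, rng)
        totals = np.zeros(6)
        for day in range(300):
            nt, _ = assign_tasks(day, crew, params, rng)
            totals += nt
        share = totals / totals.sum()
        assert np.allclose(share, 1 / 6, atol=0.01)

    def test_zero_task_day(self, params, rng):
        crew = build_crew(TeamConfiguration("A"), params, rng)
        nt, tr = assign_tasks(0, crew, params.replace(tasks_per_day_mean=0.0), rng)
        assert nt.sum() == 0 and tr.sum() == 0

    def test_workload_accrues_and_decays(self, params, rng):
        crew = build_crew(TeamConfiguration("A"), params, rng)
        _, tr = assign_tasks(0, crew, params, rng)
        cw1 = np.array([a.state.cumulative_workload for a in crew])
        assert np.allclose(cw1, tr)
        _, tr2 = assign_tasks(1, crew, params, rng)
        cw2 = np.array([a.state.cumulative_workload for a in crew])
        assert np.allclose(cw2, cw1 * (1 - params.workload_recovery_rate) + tr2)

    def test_greedy_routing_prefers_specialists(self, params, rng):
        # zero temperature: engineering tasks go to the engineers first
        p = params.replace(
            assignment_temperature=0.0,
            task_domain_weights=(1.0, 0.0, 0.0, 0.0),
            tasks_per_day_mean=2.0,
        )
        crew = build_crew(TeamConfiguration("B"), p, rng)
        engineers = {i for i, a in enumerate(crew) if a.skills.role == "engineer"}
        hits = total = 0
        for day in range(200):
            nt, _ = assign_tasks(day, crew, p, rng)
            total += nt.sum()
            hits += nt[list(engineers)].sum()
            for a in crew:  # reset load so preference is observed cleanly
                a.state.cumulative_workload = 0.0
        assert hits / total > 0.9


class TestDrawEvents:
    def test_zero_probability_keeps_list_empty(self, params, rng):
        p = params.replace(events=tuple(
            (k, e.__class__(0.0, e.magnitude, e.duration_days, e.matched_role))
            for k, e in params.events))
        active = []
        for day in range(200):
            active = draw_events(day, active, p, rng)
        assert active == []

    def test_certain_daily_event_with_unit_duration(self, params, rng):
        from marscrew.config import EventClass

        p = params.replace(events=(("equipment_failure", EventClass(1.0, 0.5, 1, "engineer")),))
        active = []
        for day in range(50):
            active = draw_events(day, active, p, rng)
            assert len(active) == 1
            assert active[0].kind == "equipment_failure"

    def test_empirical_firing_rate(self, params, rng):
        from marscrew.config import EventClass

        p = params.replace(events=(("comm_delay", EventClass(0.05, 0.3, 1, "pilot")),))
        fired = 0
        active = []
        n = 10_000
        for day in range(n):
            active = draw_events(day, active, p, rng)
            fired += len(active)
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(fired / n - 0.05) < 3 * se

    def test_duration_countdown(self, params, rng):
        ev = MissionEvent("equipment_failure", 0.5, 3, "engineer")
        p = params.replace(events=tuple(
            (k, e.__class__(0.0, e.magnitude, e.duration_days, e.matched_role))
            for k, e in params.events))
        active = [ev]
        lengths = []
        for day in range(4):
            active = draw_events(day, active, p, rng)
            lengths.append(len(active))
        assert lengths == [1, 1, 0, 0]

    def test_role_match_halves_surcharge(self, params):
        ev = [MissionEvent("health_incident", 0.4, 2, "medic")]
        assert event_surcharge(ev, {"engineer"}, params) == pytest.approx(0.4)
        assert event_surcharge(ev, {"engineer", "medic"}, params) == pytest.approx(0.2)


class TestUpdateHealth:
    def test_threshold_stress_leaves_health_unchanged(self, params):
        theta = params.health_stress_threshold
        assert update_health(0.7, theta, params) == pytest.approx(0.7)

    def test_full_health_saturates(self, params):
        assert update_health(1.0, 0.0, params) == 1.0

    def test_decline_hand_value(self, params):
        p = params.replace(health_decline_rate=0.01)
        theta = p.health_stress_threshold
        assert update_health(0.9, theta + 0.2, p) == pytest.approx(0.898)

    def test_recovery_below_threshold(self, params):
        got = update_health(0.5, 0.0, params)
        expected = 0.5 + params.health_recovery_rate * params.health_stress_threshold * 0.5
        assert got == pytest.approx(expected)


class TestFullRuns:
    def test_bit_identical_trajectories_under_same_seed(self, short_params, team):
        t1 = run_mission(team, short_params, 42)
        t2 = run_mission(team, short_params, 42)
        assert np.array_equal(t1.stress, t2.stress)
        assert np.array_equal(t1.performance, t2.performance)
        assert np.array_equal(t1.health, t2.health)
        assert np.array_equal(t1.team_cohesion, t2.team_cohesion)

    def test_recorded_day_count_and_crew_size(self, short_params, team):
        traj = run_mission(team, short_params, 1)
        assert traj.n_days == short_params.mission_days
        assert traj.n_agents == 6

    def test_boundedness_over_a_full_run(self, params, condition):
        traj = run_mission(TeamConfiguration(condition), params.replace(mission_days=500), 7)
        assert np.all((traj.stress >= 0) & (traj.stress <= 1))
        assert np.all((traj.performance > 0) & (traj.performance <= 1))
        assert np.all((traj.health >= 0) & (traj.health <= 1))
        assert np.all((traj.sleep_hours >= 4) & (traj.sleep_hours <= 8))
        assert np.all((traj.team_cohesion >= 0) & (traj.team_cohesion <= 1))

    def test_sleep_lags_stress_by_one_day(self, short_params, team):
        traj = run_mission(team, short_params, 3)
        # day 1 sleeps on the initial stress 0.2 -> full 8 hours
        assert np.allclose(traj.sleep_hours[0], 8.0)
        expected = np.clip(8.0 - 2.0 * (traj.stress[:-1] - 0.2), 4.0, 8.0)
        assert np.allclose(traj.sleep_hours[1:], expected)

    def test_identical_deterministic_agents_share_one_trajectory(self, quiet_params):
        # no trait spread, no stochastic inputs -> all six agents identical
        team = TeamConfiguration(
            "A", personality_spec={t: (m, 0.0) for t, (m, _) in
                                   TeamConfiguration("A").personality_spec.items()}
        )
        traj = run_mission(team, quiet_params, 9)
        for arr in (traj.stress, traj.performance, traj.health, traj.social_support):
            assert np.allclose(arr, arr[:, [0]])

    def test_final_stress_rises_above_baseline(self, params):
        traj = run_mission(TeamConfiguration("A"), params.replace(mission_days=500), 5)
        assert traj.final_crew_means()["stress"] > 0.2

    def test_cohesion_snapshots_are_symmetric(self, short_params, team):
        traj = run_mission(team, short_params, 2)
        assert len(traj.cohesion_snapshots) >= 1
        for day, m in traj.cohesion_snapshots.items():
            assert np.allclose(m, m.T)
            assert np.all((m >= 0) & (m <= 1))


class TestExport:
    def test_long_format_schema_and_shape(self, short_params):
        traj = run_mission(TeamConfiguration("A"), short_params, 1)
        df = trajectory_to_frame(traj, run_id="r1")
        assert list(df.columns) == ["run_id", "day", "agent_id", "metric", "value"]
        per_agent = short_params.mission_days * 6 * 8  # 8 per-agent metrics
        assert len(df) == per_agent + short_params.mission_days  # + team cohesion rows

    def test_write_round_trip_with_sidecar(self, short_params, tmp_path):
        import json

        import pandas as pd

        traj = run_mission(TeamConfiguration("B"), short_params, 4)
        out = tmp_path / "traj.csv"
        write_trajectory(traj, out, run_id="r4")
        df = pd.read_csv(out)
        assert df["value"].notna().all()
        meta = json.loads(out.with_suffix(".meta.json").read_text())
        assert meta["seed"] == 4
        assert meta["condition"] == "B"
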