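import math

import numpy as np
import pandas as pd
import pytest

from cxnav import metrics
from cxnav.config import get_preset
from cxnav.simulate import (
    AgentState,
    run_ant_homing_experiment,
    run_anemotaxis_experiment,
    run_chemotaxis_experiment,
    run_experiment,
    run_fly_integrated_experiment,
    run_manoeuvre_experiment,
    step_agent,
)


def step_distances(df):
    out = []
    for _, traj in df.groupby(["run", "agent"]):
        out.append(np.hypot(traj["x"].diff().dropna(), traj["y"].diff().dropna()))
    return np.concatenate(out)


class TestKinematics:
    def test_zero_turn_walks_straight(self):
        ag = AgentState(x=0.0, y=0.0, heading=0.0, step_length=0.5)
        for _ in range(4):
            step_agent(ag, 0.0)
        assert (ag.x, ag.y) == pytest.approx((2.0, 0.0))

    def test_four_right_angles_close_a_square(self):
        ag = AgentState(x=1.0, y=2.0, heading=0.3, step_length=0.7)
        for _ in range(4):
            step_agent(ag, math.pi / 2)
        assert math.hypot(ag.x - 1.0, ag.y - 2.0) < 1e-9

    def test_displacement_equals_preset_step_length(self):
        ag = AgentState(x=0.0, y=0.0, heading=1.0, step_length=0.02)
        dx, dy = step_agent(ag, 0.4)
        assert math.hypot(dx, dy) == pytest.approx(0.02)

    def test_non_finite_turn_rejected(self):
        ag = AgentState(x=0.0, y=0.0, heading=0.0, step_length=1.0)
        with pytest.raises(ValueError):
            step_agent(ag, math.nan)


@pytest.fixture(scope="module")
def anemo():
    return run_anemotaxis_experiment(get_preset("fly_anemotaxis", repeats=2), seed=3)


@pytest.fixture(scope="module")
def ant():
    return run_ant_homing_experiment(
        get_preset("ant_integrated", n_agents=4, steps=400), seed=1
    )


class TestRunnerContracts:

    def test_constant_speed_every_recorded_step(self, anemo):
        d = step_distances(anemo.frame)
        assert np.allclose(d, 0.4, atol=1e-12)

    def test_positions_always_finite(self, anemo):
        assert np.isfinite(anemo.frame[["x", "y", "heading", "turn"]].to_numpy()).all()

    def test_trail_length_matches_steps(self, anemo):
        counts = anemo.frame.groupby(["run", "agent"]).size()
        assert (counts == anemo.config.steps + 1).all()

    def test_same_seed_bitwise_identical(self, tmp_path):
        cfg = get_preset("fly_anemotaxis", repeats=1, steps=80)
        a, b = (run_anemotaxis_experiment(cfg, seed=9) for _ in range(2))
        pd.testing.assert_frame_equal(a.frame, b.frame)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        a.to_csv(pa), b.to_csv(pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_fewer_agents_is_prefix_subset(self):
        cfg_full = get_preset("fly_anemotaxis", repeats=1, steps=60)
        cfg_half = get_preset("fly_anemotaxis", repeats=1, steps=60, n_agents=2)
        full = run_anemotaxis_experiment(cfg_full, seed=5).frame
        half = run_anemotaxis_experiment(cfg_half, seed=5).frame
        pd.testing.assert_frame_equal(
            half, full[full["agent"] < 2].reset_index(drop=True)
        )

    def test_dispatch_matches_dedicated_runner(self):
        cfg = get_preset("ant_backtracking", n_agents=3, steps=20)
        via_dispatch = run_experiment(cfg, seed=2).frame
        direct = run_manoeuvre_experiment(cfg, seed=2).frame
        pd.testing.assert_frame_equal(via_dispatch, direct)


class TestChemotaxisRunner:
    def test_flat_zero_field_walks_straight(self):
        # 'linear' landscape with tiny k clamps to 0 everywhere inside the
        # rim: no odour change, hence never a shift, hence straight paths
        cfg = get_preset(
            "fly_chemotaxis_linear",
            field=dict(kind="linear", k=0.1),
            start_zone=(-0.1, 0.1, -0.1, 0.1),
            steps=100, repeats=1,
        )
        ts = run_chemotaxis_experiment(cfg, seed=1)
        assert np.allclose(ts.frame["turn"], 0.0, atol=1e-12)
        assert (ts.frame["concentration"] == 0.0).all()
        # headings never change, so each path is a straight line
        assert (ts.frame.groupby(["run", "agent"])["heading"].nunique() == 1).all()

    def test_agents_climb_the_volcano(self):
        cfg = get_preset("fly_chemotaxis_volcano", repeats=1)
        ts = run_chemotaxis_experiment(cfg, seed=2)
        s = ts.summary()
        start = ts.frame.groupby(["run", "agent"]).head(1)
        assert s["final_concentration"].mean() > start["concentration"].mean()


class TestAnemotaxisRunner:
    def test_gate_zeroes_odour_outside_window(self):
        cfg = get_preset("fly_anemotaxis", repeats=1)
        df = run_anemotaxis_experiment(cfg, seed=1).frame
        walking = df[df["mode"] != "END"]
        outside = walking[(walking["t"] < 50) | (walking["t"] >= 100)]
        inside = walking[(walking["t"] >= 50) & (walking["t"] < 100)]
        assert (outside["concentration"] == 0.0).all()
        assert (inside["mode"] == "ON").all()
        assert (outside["mode"] == "RANDOM").all()

    def test_rotating_the_wind_rotates_the_surge(self):
        base = get_preset("fly_anemotaxis", repeats=1)
        delta = math.radians(40)
        rotated = get_preset(
            "fly_anemotaxis", repeats=1, wind=dict(u=10.0, w_theta=-math.pi / 2 + delta)
        )
        def on_mean_heading(cfg):
            df = run_anemotaxis_experiment(cfg, seed=4).frame
            on = df[df["mode"] == "ON"]
            return metrics.circular_mean(on["heading"].to_numpy())
        got = math.remainder(on_mean_heading(rotated) - on_mean_heading(base), 2 * math.pi)
        assert got == pytest.approx(delta, abs=math.radians(8))


class TestFlyIntegratedRunner:
    def test_gate_never_open_means_no_on_events(self):
        cfg = get_preset("fly_integrated", repeats=1, odour_window=(0.0, 0.0))
        df = run_fly_integrated_experiment(cfg, seed=1).frame
        assert len(metrics.mode_events(df, "ON")) == 0
        assert (df[df["mode"] != "END"]["mode"] == "RANDOM").all()

    def test_on_events_fire_in_every_repeat_of_default_plume(self):
        # pre-gate random dispersal carries some agents out of the odour
        # wedge entirely, so ON is guaranteed per repeat, not per agent
        cfg = get_preset("fly_integrated")
        df = run_fly_integrated_experiment(cfg, seed=1).frame
        events = metrics.mode_events(df, "ON")
        assert events["run"].nunique() >= cfg.repeats - 2
        per_agent = events.groupby(["run", "agent"]).size()
        assert (per_agent >= 1).all() and len(per_agent) >= 5

    def test_plume_exit_off_events_recover(self):
        # agents that lose the plume (OFF) mostly regain odour later
        cfg = get_preset("fly_integrated")
        df = run_fly_integrated_experiment(cfg, seed=1).frame
        offs = metrics.mode_events(df, "OFF")
        recovered = 0
        for _, ev in offs.iterrows():
            traj = df[(df["run"] == ev["run"]) & (df["agent"] == ev["agent"])]
            later = traj[traj["t"] > ev["t"]]
            if (later["concentration"] > cfg.thresholds.thr_o).any():
                recovered += 1
        if len(offs):
            assert recovered / len(offs) > 0.5


class TestAntHomingRunner:
    def test_constant_speed_until_absorption(self, ant):
        assert np.allclose(step_distances(ant.frame), 0.05, atol=1e-12)

    def test_trails_truncate_at_nest_entry(self, ant):
        cfg = ant.config
        for _, traj in ant.frame.groupby(["run", "agent"]):
            last = traj.iloc[-1]
            arrived = math.hypot(last["x"], last["y"]) < cfg.arrival_radius
            assert arrived or last["t"] == cfg.steps
            # no recorded point before the end is inside the nest area
            body = traj.iloc[:-1]
            assert (np.hypot(body["x"], body["y"]) >= cfg.arrival_radius).all()

    def test_early_group_heading_follows_home_vector(self, ant):
        gh = metrics.group_heading(ant.frame, 20)
        assert abs(math.remainder(gh - math.pi / 2, 2 * math.pi)) < math.radians(15)


class TestManoeuvreRunner:
    def test_backtracking_group_settles_opposite_capture(self):
        cfg = get_preset("ant_backtracking")
        df = run_manoeuvre_experiment(cfg, seed=1).frame
        last = df[df["mode"] != "END"].groupby("agent").tail(1)["heading"].to_numpy()
        mean = metrics.circular_mean(last)
        assert abs(math.remainder(mean - (-math.pi / 2), 2 * math.pi)) < math.radians(5)

    def test_steering_concentrates_uniform_headings(self):
        cfg = get_preset("ant_wind_compensation")
        df = run_manoeuvre_experiment(cfg, seed=1).frame
        first = df[df["t"] == 0]["heading"].to_numpy()
        last = df[df["mode"] != "END"].groupby("agent").tail(1)["heading"].to_numpy()
        assert metrics.circular_variance(last) < 0.1 * metrics.circular_variance(first)

    def test_unknown_kind_rejected(self):
        cfg = get_preset("ant_backtracking")
        with pytest.raises(ValueError):
            run_manoeuvre_experiment(cfg, kind="teleport", seed=1)


class TestMetrics:
    def test_straight_path_has_zero_angular_velocity(self):
        ag = AgentState(x=0.0, y=0.0, heading=0.7, step_length=1.0)
        for t in range(10):
            ag.record(0, 0, t, 0.0, 0.0, "X", 0.0)
            step_agent(ag, 0.0)
        df = pd.DataFrame(ag.trail, columns=[
            "run", "agent", "t", "x", "y", "heading", "concentration",
            "delta_c", "mode", "turn",
        ])
        assert (df["turn"] == 0.0).all()

    def test_upwind_motion_scores_full_step_length(self):
        df = pd.DataFrame({"heading": [math.pi / 2] * 5})
        up = metrics.upwind_speed(df, wind_dir=-math.pi / 2, step_length=0.4)
        assert np.allclose(up, 0.4)

    def test_circular_mean_of_perpendicular_headings(self):
        assert metrics.circular_mean([0.0, math.pi / 2]) == pytest.approx(math.pi / 4)

    def test_circular_mean_of_opposed_headings_is_undefined(self):
        assert math.isnan(metrics.circular_mean([0.0, math.pi]))
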