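"""Summary metrics over trajectory tables.

Trajectories are tidy pandas DataFrames with one row per (run, agent,
step); see :mod:`cxnav.simulate` for the column schema.  Circular
statistics use the standard resultant-vector definitions.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "circular_mean",
    "circular_variance",
    "angular_distance",
    "upwind_speed",
    "path_length",
    "group_heading",
    "mode_events",
    "summarise",
]


def circular_mean(angles, weights=None) -> float:
    """Direction of the (weighted) resultant vector; nan if it vanishes."""
    a = np.asarray(angles, dtype=float)
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    x, y = float(np.sum(w * np.cos(a))), float(np.sum(w * np.sin(a)))
    if math.hypot(x, y) < 1e-12 * max(1.0, float(np.sum(np.abs(w)))):
        return float("nan")
    return math.atan2(y, x)


def circular_variance(angles) -> float:
    """1 - mean resultant length, in [0, 1] (0 = perfectly concentrated)."""
    a = np.asarray(angles, dtype=float)
    r = math.hypot(float(np.mean(np.cos(a))), float(np.mean(np.sin(a))))
    return 1.0 - r


def angular_distance(a: float, b: float) -> float:
    """Absolute angular separation in [0, pi]."""
    return abs(math.remainder(a - b, 2.0 * math.pi))


def upwind_speed(df: pd.DataFrame, wind_dir: float, step_length: float) -> pd.Series:
    """Per-step velocity component along the upwind direction (wind_dir + pi)."""
    up = wind_dir + math.pi
    return step_length * np.cos(df["heading"] - up)


def path_length(df: pd.DataFrame) -> float:
    """Total distance walked by one agent's trajectory (rows of one agent)."""
    dx = df["x"].diff().dropna()
    dy = df["y"].diff().dropna()
    return float(np.hypot(dx, dy).sum())


def group_heading(df: pd.DataFrame, t: int) -> float:
    """Circular mean heading over all agents at step ``t``."""
    snap = df[df["t"] == t]
    if snap.empty:
        raise ValueError(f"no rows at t={t}")
    return circular_mean(snap["heading"].to_numpy())


def mode_events(df: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Steps at which an agent's behavioural mode switches *into* ``mode``."""
    rows = []
    for (run, agent), traj in df.groupby(["run", "agent"], sort=True):
        m = traj.sort_values("t")
        entered = (m["mode"] == mode) & (m["mode"].shift(fill_value="") != mode)
        for t in m.loc[entered, "t"]:
            rows.append({"run": run, "agent": agent, "t": int(t), "mode": mode})
    return pd.DataFrame(rows, columns=["run", "agent", "t", "mode"])


def summarise(df: pd.DataFrame) -> pd.DataFrame:
    """Per-agent endpoint summary: final position/heading/concentration, path length."""
    out = []
    for (run, agent), traj in df.groupby(["run", "agent"], sort=True):
        traj = traj.sort_values("t")
        last = traj.iloc[-1]
        out.append(
            {
                "run": run,
                "agent": agent,
                "final_x": last["x"],
                "final_y": last["y"],
                "final_heading": last["heading"],
                "final_concentration": last["concentration"],
                "path_length": path_length(traj),
                "mean_abs_turn": float(traj["turn"].abs().mean()),
            }
        )
    return pd.DataFrame(out)


def experiment_metrics(ts) -> dict:
    """Headline numbers for one TrajectorySet, keyed by experiment kind."""
    cfg = ts.config
    df = ts.frame
    summary = summarise(df)
    out = {
        "experiment": cfg.experiment,
        "preset": cfg.name,
        "seed": ts.seed,
        "n_trajectories": int(len(summary)),
        "mean_path_length": float(summary["path_length"].mean()),
    }
    if cfg.experiment == "chemotaxis":
        out["mean_final_concentration"] = float(summary["final_concentration"].mean())
        out["frac_final_above_09k"] = float(
            (summary["final_concentration"] > 0.9 * cfg.field.k).mean()
        )
    elif cfg.experiment in ("anemotaxis", "fly_integrated"):
        on = df[df["mode"] == "ON"]
        off = df[df["mode"].isin(["RANDOM", "OFF"])]
        if len(on) and len(off):
            out["mean_upwind_speed_on"] = float(
                upwind_speed(on, cfg.wind.w_theta, cfg.step_length).mean()
            )
            out["mean_upwind_speed_off"] = float(
                upwind_speed(off, cfg.wind.w_theta, cfg.step_length).mean()
            )
            out["mean_abs_angvel_on"] = float(on["turn"].abs().mean())
            out["mean_abs_angvel_off"] = float(off["turn"].abs().mean())
        out["n_on_events"] = int(len(mode_events(df, "ON")))
        out["n_off_events"] = int(len(mode_events(df, "OFF")))
    elif cfg.experiment == "ant_homing":
        nest = cfg.field.source
        dist = np.hypot(summary["final_x"] - nest[0], summary["final_y"] - nest[1])
        out["frac_arrived"] = float((dist <= cfg.arrival_radius).mean())
        out["group_heading_t20_deg"] = math.degrees(group_heading(df, 20))
        walking = df[(df["t"] == 250) & (df["mode"] != "END")]
        if len(walking):
            out["group_heading_t250_deg"] = math.degrees(
                circular_mean(walking["heading"].to_numpy())
            )
    elif cfg.experiment in ("wind_compensation", "backtracking"):
        last = df[df["mode"] != "END"].groupby("agent").tail(1)["heading"].to_numpy()
        out["settled_heading_deg"] = math.degrees(circular_mean(last))
        out["settled_circular_variance"] = float(circular_variance(last))
    return out
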