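"""Agent kinematics and the experiment runners.

An agent is a point walker with constant step length: at each step it
senses the odour field at its position, updates its neural state to pick
a turn, rotates by the (capped) turn, and moves one step length along its
new heading.  The unit of time is one step; speeds are length units per
step.

Runners reproduce the published simulation protocols:

* :func:`run_chemotaxis_experiment` — windless gradient ascent, 5 agents
  x 1500 steps x 4 repeats per landscape.
* :func:`run_anemotaxis_experiment` — odour-gated upwind surging in a
  plume; odour ON only during the second quarter of the run.
* :func:`run_fly_integrated_experiment` — full ON/OFF switching between
  anemotaxis, chemotaxis and undirected walking.
* :func:`run_ant_homing_experiment` — path integration fused with
  odour-gated olfactory guidance by the ring attractor, with an optional
  conspecific-nest distractor plume.
* :func:`run_manoeuvre_experiment` — wind-compensation / backtracking
  dashes steered from a stored working-memory heading.

Each returns a :class:`TrajectorySet` whose ``frame`` is a tidy
DataFrame with one row per (run, agent, t):

    run, agent, t, x, y, heading, concentration, delta_c, mode, turn

Row ``t`` holds the position at which the agent sensed, the mode and turn
it chose, and the heading it then walked along; the last row (mode
``END``) is the final position.  Identical (config, seed) pairs give
bit-identical tables, and agents are seeded independently so reducing
``n_agents`` yields a prefix subset of the runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import metrics
from .config import ExperimentConfig
from .fields import sample_with_memory
from .guidance import (
    GuidanceMode,
    anemotaxis_heading,
    chemotaxis_heading,
    classify_response,
    integrate_pi_olfaction,
    normalise_desired,
    pi_update,
    PIMemory,
    project_to_steering,
    random_heading,
)
from .manoeuvres import (
    form_backtracking_memory,
    form_wind_compensation_memory,
    navigate_from_memory,
)
from .rings import encode_heading, wpn_response, wrap_angle

__all__ = [
    "TrajectorySet",
    "step_agent",
    "AgentState",
    "run_chemotaxis_experiment",
    "run_anemotaxis_experiment",
    "run_fly_integrated_experiment",
    "run_ant_homing_experiment",
    "run_manoeuvre_experiment",
    "run_experiment",
]

COLUMNS = ["run", "agent", "t", "x", "y", "heading", "concentration", "delta_c", "mode", "turn"]


@dataclass
class AgentState:
    """Pose and per-step trail of one agent."""

    x: float
    y: float
    heading: float
    step_length: float
    trail: list = dc_field(default_factory=list)

    def record(self, run, agent, t, c, delta_c, mode, turn, pos=None):
        x, y = (self.x, self.y) if pos is None else pos
        self.trail.append(
            (run, agent, t, x, y, self.heading, c, delta_c, mode, turn)
        )


def step_agent(agent: AgentState, turn: float) -> tuple[float, float]:
    """Apply a turn and advance one step length; returns the displacement."""
    if not math.isfinite(turn):
        raise ValueError("turn must be finite")
    agent.heading = wrap_angle(agent.heading + turn)
    dx = agent.step_length * math.cos(agent.heading)
    dy = agent.step_length * math.sin(agent.heading)
    agent.x += dx
    agent.y += dy
    return dx, dy


@dataclass(frozen=True)
class TrajectorySet:
    """Trajectories of one experiment plus the config that produced them."""

    frame: pd.DataFrame
    config: ExperimentConfig
    seed: int

    def to_csv(self, path):
        self.frame.to_csv(path, index=False, float_format="%.10g")

    def summary(self) -> pd.DataFrame:
        return metrics.summarise(self.frame)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(seed)] + [int(k) for k in key])


def _finish(rows, config, seed) -> TrajectorySet:
    frame = pd.DataFrame(rows, columns=COLUMNS)
    return TrajectorySet(frame=frame, config=config, seed=seed)


def _init_agent(config: ExperimentConfig, rng: np.random.Generator) -> AgentState:
    x0, x1, y0, y1 = config.start_zone
    return AgentState(
        x=rng.uniform(x0, x1),
        y=rng.uniform(y0, y1),
        heading=rng.uniform(0.0, 2.0 * math.pi),
        step_length=config.step_length,
    )


def _capped(turn: float, cap: float) -> float:
    return max(-cap, min(cap, turn))


# ---------------------------------------------------------------------------
# Fly: chemotaxis in windless gradients

def run_chemotaxis_experiment(config: ExperimentConfig, seed: int | None = None) -> TrajectorySet:
    """Pure chemotaxis: the drop-driven copy-and-shift is the only guidance."""
    seed = config.seed if seed is None else seed
    fields = config.make_fields()
    rows = []
    for rep in range(config.repeats):
        for a in range(config.n_agents):
            rng = _rng(seed, rep, a)
            ag = _init_agent(config, rng)
            prev_c = None
            for t in range(config.steps):
                c, dc = sample_with_memory(fields, (ag.x, ag.y), prev_c)
                prev_c = c
                current = encode_heading(ag.heading)
                desired = chemotaxis_heading(
                    current, dc, config.k_chemo,
                    config.chemo_direction, config.chemo_sign_convention,
                )
                turn = _capped(
                    project_to_steering(desired, current, config.k_motor).turn_angle,
                    config.turn_cap,
                )
                pos = (ag.x, ag.y)
                step_agent(ag, turn)
                ag.record(rep, a, t, c, dc, "CHEMO", turn, pos=pos)
            c, dc = sample_with_memory(fields, (ag.x, ag.y), prev_c)
            ag.record(rep, a, config.steps, c, dc, "END", 0.0)
            rows.extend(ag.trail)
    return _finish(rows, config, seed)


# ---------------------------------------------------------------------------
# Fly: odour-gated anemotaxis

def _odour_gate(config: ExperimentConfig, t: int) -> float:
    if config.odour_window is None:
        return 1.0
    lo, hi = config.odour_window
    return 1.0 if lo * config.steps <= t < hi * config.steps else 0.0


def run_anemotaxis_experiment(config: ExperimentConfig, seed: int | None = None) -> TrajectorySet:
    """Upwind surging while the odour gate is ON; undirected walk otherwise."""
    seed = config.seed if seed is None else seed
    fields = config.make_fields()
    w = config.wind
    rows = []
    for rep in range(config.repeats):
        for a in range(config.n_agents):
            rng = _rng(seed, rep, a)
            ag = _init_agent(config, rng)
            prev_c = None
            for t in range(config.steps):
                gate = _odour_gate(config, t)
                raw, _ = sample_with_memory(fields, (ag.x, ag.y), None)
                c, dc = gate * raw, 0.0
                if prev_c is not None:
                    dc = c - prev_c
                prev_c = c
                current = encode_heading(ag.heading)
                if gate > 0.0:
                    wind = wpn_response(w.w_theta, ag.heading)
                    desired = anemotaxis_heading(current, wind)
                    mode = "ON"
                else:
                    desired = random_heading(ag.heading, rng, config.random_jitter)
                    mode = "RANDOM"
                turn = _capped(
                    project_to_steering(desired, current, config.k_motor).turn_angle,
                    config.turn_cap,
                )
                pos = (ag.x, ag.y)
                step_agent(ag, turn)
                ag.record(rep, a, t, c, dc, mode, turn, pos=pos)
            ag.record(rep, a, config.steps, prev_c, 0.0, "END", 0.0)
            rows.extend(ag.trail)
    return _finish(rows, config, seed)


# ---------------------------------------------------------------------------
# Fly: integrated ON/OFF switching

def run_fly_integrated_experiment(config: ExperimentConfig, seed: int | None = None) -> TrajectorySet:
    """Truth-table switching between anemotaxis (ON), chemotaxis (OFF) and random walk."""
    seed = config.seed if seed is None else seed
    fields = config.make_fields()
    w = config.wind
    thr = config.make_thresholds()
    rows = []
    for rep in range(config.repeats):
        for a in range(config.n_agents):
            rng = _rng(seed, rep, a)
            ag = _init_agent(config, rng)
            prev_c = None
            for t in range(config.steps):
                gate = _odour_gate(config, t)
                raw, _ = sample_with_memory(fields, (ag.x, ag.y), None)
                c = gate * raw
                dc = 0.0 if prev_c is None else c - prev_c
                prev_c = c
                mode = classify_response(c, dc, thr)
                current = encode_heading(ag.heading)
                if mode is GuidanceMode.ON:
                    wind = wpn_response(w.w_theta, ag.heading)
                    desired = anemotaxis_heading(current, wind)
                elif mode is GuidanceMode.OFF:
                    desired = chemotaxis_heading(
                        current, dc, config.k_chemo,
                        config.chemo_direction, config.chemo_sign_convention,
                    )
                else:
                    desired = random_heading(ag.heading, rng, config.random_jitter)
                turn = _capped(
                    project_to_steering(desired, current, config.k_motor).turn_angle,
                    config.turn_cap,
                )
                pos = (ag.x, ag.y)
                step_agent(ag, turn)
                ag.record(rep, a, t, c, dc, mode.value, turn, pos=pos)
            ag.record(rep, a, config.steps, prev_c, 0.0, "END", 0.0)
            rows.extend(ag.trail)
    return _finish(rows, config, seed)


# ---------------------------------------------------------------------------
# Ant: PI + olfaction fused by the ring attractor

def run_ant_homing_experiment(config: ExperimentConfig, seed: int | None = None) -> TrajectorySet:
    """Full-vector ants homing on PI with odour-gated olfactory guidance.

    Agents start at each release point with uniformly random headings and
    an identical full home vector; runs are indexed by release point.  The
    nest is absorbing: a trail ends (END row) at the first step within
    ``config.arrival_radius`` of the home-plume source, so recorded path
    length is the path walked to arrival.
    """
    seed = config.seed if seed is None else seed
    fields = config.make_fields()
    w = config.wind
    thr = config.make_thresholds()
    ra = config.make_ra_params()
    pi0 = PIMemory(
        home_vector=(
            config.pi.length * math.cos(config.pi.direction),
            config.pi.length * math.sin(config.pi.direction),
        ),
        reference_length=config.pi.length,
    )
    rows = []
    for ridx, release in enumerate(config.release_points):
        for a in range(config.n_agents):
            rng = _rng(seed, ridx, a)
            ag = AgentState(
                x=release[0], y=release[1],
                heading=rng.uniform(0.0, 2.0 * math.pi),
                step_length=config.step_length,
            )
            pi = pi0
            prev_c = None
            nest = config.field.source
            arrived = False
            for t in range(config.steps):
                if math.hypot(ag.x - nest[0], ag.y - nest[1]) < config.arrival_radius:
                    c, dc = sample_with_memory(fields, (ag.x, ag.y), prev_c)
                    ag.record(ridx, a, t, c, dc, "END", 0.0)
                    arrived = True
                    break
                c, dc = sample_with_memory(fields, (ag.x, ag.y), prev_c)
                prev_c = c
                mode = classify_response(c, dc, thr)
                current = encode_heading(ag.heading)
                chemo = chemotaxis_heading(
                    current, dc, config.k_chemo,
                    config.chemo_direction, config.chemo_sign_convention,
                )
                wind = wpn_response(w.w_theta, ag.heading)
                anemo = anemotaxis_heading(current, wind)
                explore = random_heading(ag.heading, rng, config.random_jitter)
                fused = integrate_pi_olfaction(
                    pi.ring(), mode, chemo, anemo, c, config.k_o, ra,
                    exploration_ring=explore,
                )
                turn = _capped(
                    project_to_steering(
                        normalise_desired(fused), current, config.k_motor
                    ).turn_angle,
                    config.turn_cap,
                )
                pos = (ag.x, ag.y)
                dx, dy = step_agent(ag, turn)
                pi = pi_update(pi, (dx, dy))
                ag.record(ridx, a, t, c, dc, mode.value, turn, pos=pos)
            if not arrived:
                c, dc = sample_with_memory(fields, (ag.x, ag.y), prev_c)
                ag.record(ridx, a, config.steps, c, dc, "END", 0.0)
            rows.extend(ag.trail)
    return _finish(rows, config, seed)


# ---------------------------------------------------------------------------
# Ant: working-memory manoeuvres

def run_manoeuvre_experiment(
    config: ExperimentConfig, kind: str | None = None, seed: int | None = None
) -> TrajectorySet:
    """Wind-compensation or backtracking dash steered from working memory.

    The memory is formed once, at the scripted trigger, from the capture
    heading (and the wind, for wind compensation); agents are then
    released with uniformly random initial headings and steered purely
    from the stored bump.
    """
    seed = config.seed if seed is None else seed
    kind = kind or config.experiment
    if kind not in ("wind_compensation", "backtracking"):
        raise ValueError(f"unknown manoeuvre kind {kind!r}")
    compass_at_capture = encode_heading(config.capture_heading)
    if kind == "wind_compensation":
        wind = wpn_response(config.wind.w_theta, config.capture_heading)
        memory = form_wind_compensation_memory(compass_at_capture, wind)
    else:
        memory = form_backtracking_memory(compass_at_capture)
    release = config.release_points[0] if config.release_points else (0.0, 0.0)
    rows = []
    for a in range(config.n_agents):
        rng = _rng(seed, a)
        ag = AgentState(
            x=release[0], y=release[1],
            heading=rng.uniform(0.0, 2.0 * math.pi),
            step_length=config.step_length,
        )
        for t in range(config.steps):
            current = encode_heading(ag.heading)
            turn = _capped(
                navigate_from_memory(memory, current, config.k_motor).turn_angle,
                config.turn_cap,
            )
            pos = (ag.x, ag.y)
            step_agent(ag, turn)
            ag.record(0, a, t, 0.0, 0.0, kind.upper(), turn, pos=pos)
        ag.record(0, a, config.steps, 0.0, 0.0, "END", 0.0)
        rows.extend(ag.trail)
    return _finish(rows, config, seed)


_RUNNERS = {
    "chemotaxis": run_chemotaxis_experiment,
    "anemotaxis": run_anemotaxis_experiment,
    "fly_integrated": run_fly_integrated_experiment,
    "ant_homing": run_ant_homing_experiment,
    "wind_compensation": run_manoeuvre_experiment,
    "backtracking": run_manoeuvre_experiment,
}


def run_experiment(config: ExperimentConfig, seed: int | None = None) -> TrajectorySet:
    """Dispatch a config to its experiment runner."""
    return _RUNNERS[config.experiment](config, seed=seed)
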