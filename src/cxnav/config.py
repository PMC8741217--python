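"""Experiment configuration schema and the preset library.

Configs are plain YAML mappings validated by a closed pydantic schema
(unknown keys are rejected by name).  A file may name a ``preset`` and
override individual keys:

.. code-block:: yaml

    preset: fly_anemotaxis
    steps: 400
    k_motor: 1.5

Angles may be written as numbers (radians) or as strings in units of pi
(``"-0.5pi"``, ``"pi"``, ``"0.25 pi"``) so presets like a wind direction
of -pi/2 are exact.

The seven presets bind every symbol of the published parameter table:
odour-field scale ``k``, decay ``tau``, source radius ``r``, emission
rate ``q``, wind speed ``u`` and direction ``w_theta``, switching
thresholds ``thr_o`` / ``thr_on`` / ``thr_off``, gains ``k_o`` /
``k_chemo`` / ``k_motor``, and step length ``SL``.
"""

from __future__ import annotations

import math
import re
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .fields import PLUME_KS_CHOICES, GradientField, PlumeField

__all__ = ["ExperimentConfig", "load_config", "dump_config", "preset_names", "get_preset"]

_PI_RE = re.compile(r"^\s*(-?\d*\.?\d*)\s*pi\s*$")


def parse_angle(value) -> float:
    """Parse an angle given in radians or as a multiple of pi ('-0.5pi')."""
    if isinstance(value, str):
        m = _PI_RE.match(value)
        if not m:
            raise ValueError(f"cannot parse angle {value!r}")
        coeff = m.group(1)
        if coeff in ("", "-"):
            coeff += "1"
        return float(coeff) * math.pi
    return float(value)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class FieldConfig(_Strict):
    """Odour-landscape parameters (gradient or plume)."""

    kind: Literal["volcano", "linear", "plume"]
    k: float = 10.0
    tau: float = 0.1
    r: float = 6.0
    q: float = 10.0
    ks: float = 0.2
    spread: Literal["downwind", "crosswind"] = "downwind"
    source: tuple[float, float] = (0.0, 0.0)

    @field_validator("ks")
    @classmethod
    def _ks_admissible(cls, v):
        if not any(math.isclose(v, c) for c in PLUME_KS_CHOICES):
            raise ValueError(f"ks must be one of {PLUME_KS_CHOICES}")
        return v


class WindConfig(_Strict):
    """Constant airflow: speed ``u`` and the direction the air flows toward."""

    u: float = 10.0
    w_theta: float = -math.pi / 2

    @field_validator("w_theta", mode="before")
    @classmethod
    def _angle(cls, v):
        return parse_angle(v)


class ThresholdConfig(_Strict):
    """ON/OFF switching thresholds."""

    thr_o: float
    thr_on: float
    thr_off: float

    @model_validator(mode="after")
    def _signs(self):
        if not (self.thr_off < 0.0 < self.thr_on):
            raise ValueError("thr_off must be negative and thr_on positive")
        return self


class RAConfig(_Strict):
    """Ring-attractor network parameters (see rings.RingAttractorParams)."""

    tau: float = 1.0
    rho: float = 0.1
    w0: float = -0.05
    w1: float = 0.15
    w_i2e: float = -0.2
    dt: float = 0.1
    tol: float = 1e-5
    max_steps: int = 500


class PIConfig(_Strict):
    """Initial path-integration memory (home-vector length and direction)."""

    length: float = 10.0
    direction: float = math.pi / 2

    @field_validator("direction", mode="before")
    @classmethod
    def _angle(cls, v):
        return parse_angle(v)


class DistractorConfig(_Strict):
    """Conspecific-nest plume added to the ant arena."""

    enabled: bool = True
    source: tuple[float, float] = (-1.0, -8.0)
    q: float = 20.0


class ExperimentConfig(_Strict):
    """Complete, validated description of one simulation experiment."""

    name: str = "custom"
    experiment: Literal[
        "chemotaxis",
        "anemotaxis",
        "fly_integrated",
        "ant_homing",
        "wind_compensation",
        "backtracking",
    ]
    field: Optional[FieldConfig] = None
    wind: Optional[WindConfig] = None
    thresholds: Optional[ThresholdConfig] = None
    ra: RAConfig = RAConfig()
    pi: Optional[PIConfig] = None
    distractor: Optional[DistractorConfig] = None

    k_chemo: float = 100.0
    k_o: float = 0.5
    k_motor: float = 1.0
    step_length: float = 0.02
    steps: int = 1500
    n_agents: int = 5
    repeats: int = 1
    start_zone: tuple[float, float, float, float] = (-12.0, 12.0, -12.0, 12.0)
    release_points: tuple[tuple[float, float], ...] = ()
    capture_heading: float = math.pi / 2
    odour_window: Optional[tuple[float, float]] = None  # fractions of the run
    arrival_radius: float = 0.5  # absorbing nest-area radius (ant homing)
    chemo_direction: Literal["left", "right"] = "left"
    chemo_sign_convention: Literal["drop", "printed"] = "drop"
    random_jitter: float = math.radians(30)
    turn_cap: float = math.pi / 2
    seed: int = 0

    @field_validator("capture_heading", mode="before")
    @classmethod
    def _angle(cls, v):
        return parse_angle(v)

    @model_validator(mode="after")
    def _coherent(self):
        needs_field = self.experiment in ("chemotaxis", "anemotaxis", "fly_integrated", "ant_homing")
        if needs_field and self.field is None:
            raise ValueError(f"experiment {self.experiment!r} requires a field")
        if self.experiment in ("anemotaxis", "fly_integrated", "ant_homing", "wind_compensation"):
            if self.wind is None:
                raise ValueError(f"experiment {self.experiment!r} requires wind")
        if self.experiment in ("fly_integrated", "ant_homing") and self.thresholds is None:
            raise ValueError(f"experiment {self.experiment!r} requires thresholds")
        if self.experiment == "ant_homing" and (self.pi is None or not self.release_points):
            raise ValueError("ant_homing requires pi memory and release_points")
        if self.steps < 1 or self.n_agents < 1 or self.repeats < 1:
            raise ValueError("steps, n_agents and repeats must be >= 1")
        if self.step_length <= 0:
            raise ValueError("step_length must be positive")
        return self

    # -- instantiation helpers -------------------------------------------

    def make_fields(self) -> list:
        """Build the odour field objects (main field plus any distractor)."""
        if self.field is None:
            return []
        f = self.field
        if f.kind in ("volcano", "linear"):
            flds = [GradientField(kind=f.kind, k=f.k, tau=f.tau, r=f.r, source=f.source)]
        else:
            w = self.wind
            flds = [
                PlumeField(
                    q=f.q, wind_speed=w.u, wind_dir=w.w_theta, ks=f.ks,
                    source=f.source, guard_radius=self.step_length,
                    spread=f.spread,
                )
            ]
            if self.distractor is not None and self.distractor.enabled:
                flds.append(
                    PlumeField(
                        q=self.distractor.q, wind_speed=w.u, wind_dir=w.w_theta,
                        ks=f.ks, source=self.distractor.source,
                        guard_radius=self.step_length, spread=f.spread,
                    )
                )
        return flds

    def make_ra_params(self):
        from .rings import RingAttractorParams

        r = self.ra
        return RingAttractorParams(
            tau=r.tau, rho=r.rho, w0=r.w0, w1=r.w1, w_i2e=r.w_i2e,
            dt=r.dt, tol=r.tol, max_steps=r.max_steps,
        )

    def make_thresholds(self):
        from .guidance import SwitchThresholds

        t = self.thresholds
        return SwitchThresholds(thr_o=t.thr_o, thr_on=t.thr_on, thr_off=t.thr_off)


# ---------------------------------------------------------------------------
# Preset library — every published parameter-table symbol bound by name.

PRESETS: dict[str, dict] = {
    "fly_chemotaxis_volcano": dict(
        experiment="chemotaxis",
        field=dict(kind="volcano", k=10.0, tau=0.1, r=6.0),
        k_chemo=100.0, k_motor=1.0, step_length=0.02,
        steps=1500, n_agents=5, repeats=4,
        start_zone=(-12.0, 12.0, -12.0, 12.0),
    ),
    "fly_chemotaxis_linear": dict(
        experiment="chemotaxis",
        field=dict(kind="linear", k=10.0, tau=0.1, r=6.0),
        k_chemo=100.0, k_motor=1.0, step_length=0.02,
        steps=1500, n_agents=5, repeats=4,
        start_zone=(-12.0, 12.0, -12.0, 12.0),
    ),
    "fly_anemotaxis": dict(
        experiment="anemotaxis",
        field=dict(kind="plume", q=10.0, ks=0.2),
        wind=dict(u=10.0, w_theta="-0.5pi"),
        k_motor=1.5, step_length=0.4,
        steps=200, n_agents=4, repeats=5,
        start_zone=(-1.5, 1.5, -13.0, -5.0),
        odour_window=(0.25, 0.5),
    ),
    "fly_integrated": dict(
        experiment="fly_integrated",
        field=dict(kind="plume", q=10.0, ks=0.2),
        wind=dict(u=10.0, w_theta="-0.5pi"),
        thresholds=dict(thr_o=0.001, thr_on=0.02, thr_off=-0.0002),
        k_chemo=100.0, k_motor=1.5, step_length=0.4,
        steps=200, n_agents=4, repeats=5,
        start_zone=(-1.5, 1.5, -13.0, -5.0),
        odour_window=(0.25, 0.5),
    ),
    # wind blows from the nest toward the release zone so that both
    # release groups approach from downwind and can smell the nest plume;
    # upwind surging during ON responses then points at the nest.  The
    # nest plume uses the crosswind-band spread: an odour band of
    # constant width running the whole downwind half-plane, making the
    # nest smellable all along the homing route (with the
    # distance-widening Gaussian the published odour threshold is only
    # exceeded in a strip ~0.6 m wide and ~3 m long at the nest, which
    # neither release group would ever encounter)
    "ant_integrated": dict(
        experiment="ant_homing",
        field=dict(kind="plume", q=20.0, ks=0.2, spread="crosswind"),
        wind=dict(u=10.0, w_theta="-0.5pi"),
        thresholds=dict(thr_o=1.2, thr_on=0.5, thr_off=-0.0002),
        pi=dict(length=10.0, direction="0.5pi"),
        distractor=dict(enabled=True, source=(-1.0, -8.0), q=20.0),
        k_o=0.5, k_chemo=100.0, k_motor=1.0, step_length=0.05,
        steps=1200, n_agents=10, repeats=1,
        release_points=((-1.5, -10.0), (1.5, -10.0)),
    ),
    "ant_wind_compensation": dict(
        experiment="wind_compensation",
        wind=dict(u=10.0, w_theta=0.0),
        capture_heading="0.5pi",
        k_motor=1.0, step_length=0.05,
        steps=100, n_agents=20, repeats=1,
        release_points=((0.0, -10.0),),
    ),
    "ant_backtracking": dict(
        experiment="backtracking",
        capture_heading="0.5pi",
        k_motor=1.0, step_length=0.05,
        steps=100, n_agents=20, repeats=1,
        release_points=((0.0, -10.0),),
    ),
}


def preset_names() -> list[str]:
    return sorted(PRESETS)


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = val
    return out


def get_preset(name: str, **overrides) -> ExperimentConfig:
    """Instantiate a named preset, with optional field-level overrides."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {preset_names()}")
    data = _deep_merge(PRESETS[name], overrides)
    data.setdefault("name", name)
    return ExperimentConfig(**data)


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML experiment config (preset + overrides)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    preset = data.pop("preset", None)
    if preset is not None:
        return get_preset(preset, **data)
    return ExperimentConfig(**data)


def dump_config(config: ExperimentConfig, path=None) -> str:
    """Serialise a config to YAML; round-trips through load_config."""
    text = yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
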