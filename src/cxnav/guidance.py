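"""Behaviour generators: the elemental guidance systems.

Each generator emits a *desired heading* as an 8-column ring, all in the
shared geocentric compass frame established by copy-and-shift:

* **Chemotaxis** (OFF response) — keep the current heading while odour
  concentration is non-decreasing; on a drop, shift the desired heading by
  an amount proportional to the drop (saturating at 3 native columns =
  135 deg) in a predefined turn direction.
* **Anemotaxis** (ON response) — the desired heading is the geocentric
  upwind direction derived from the wedge-projection-neuron signal.
* **RANDOM** — no reliable odour signal: a correlated random walk.
* **Path integration** — a continuously updated home vector, emitted as a
  ring whose amplitude is the remaining vector length normalised by a
  reference length (1 at release, 0 at the nest).

The ON/OFF/RANDOM arbitration is the truth table over sensed
concentration and its one-step change; within a context, cues are fused
by the fan-shaped-body ring attractor, each weighted by its amplitude.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

import numpy as np

from .rings import (
    RingAttractorParams,
    SteeringOutput,
    WindSensorOutput,
    copy_and_shift,
    encode_heading,
    ring_attractor_integrate,
    steer,
    upwind_ring,
)

__all__ = [
    "GuidanceMode",
    "SwitchThresholds",
    "classify_response",
    "chemotaxis_heading",
    "anemotaxis_heading",
    "random_heading",
    "PIMemory",
    "pi_update",
    "integrate_pi_olfaction",
    "project_to_steering",
]

MAX_SHIFT_COLUMNS = 3  # chemotaxis shift saturates at 3 * 45 deg = 135 deg
COLUMN_ANGLE = math.pi / 4


class GuidanceMode(enum.Enum):
    ON = "ON"
    OFF = "OFF"
    RANDOM = "RANDOM"


@dataclass(frozen=True)
class SwitchThresholds:
    """Concentration / concentration-change thresholds of the switching circuit."""

    thr_o: float
    thr_on: float
    thr_off: float

    def __post_init__(self):
        if not (self.thr_off < 0.0 < self.thr_on):
            raise ValueError("need thr_off < 0 < thr_on")


def classify_response(c: float, delta_c: float, thr: SwitchThresholds) -> GuidanceMode:
    """ON/OFF/RANDOM arbitration truth table.

    ============  ============  ================  ===========
    concentration  dC < thr_off  thr_off..thr_on   dC >= thr_on
    ============  ============  ================  ===========
    c <  thr_o     RANDOM        RANDOM            ON
    c >= thr_o     OFF           ON                ON
    ============  ============  ================  ===========
    """
    if delta_c >= thr.thr_on:
        return GuidanceMode.ON
    if c < thr.thr_o:
        return GuidanceMode.RANDOM
    return GuidanceMode.OFF if delta_c < thr.thr_off else GuidanceMode.ON


def chemotaxis_heading(
    current,
    delta_c: float,
    k_chemo: float,
    direction: str = "left",
    sign_convention: str = "drop",
) -> np.ndarray:
    """Desired heading of the chemotactic (OFF-response) system.

    A copy of the current heading, shifted by
    ``min(k_chemo * drop, 3) * 45 deg`` in the predefined ``direction``
    ("left" = counter-clockwise), where ``drop`` is the magnitude of the
    concentration decrease; no shift while concentration is non-decreasing.
    ``sign_convention="printed"`` instead shifts on an increase (the
    literal reading of the shift rule, kept for comparison).
    """
    if k_chemo <= 0:
        raise ValueError("k_chemo must be positive")
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    if sign_convention == "drop":
        drive = max(0.0, -delta_c)
    elif sign_convention == "printed":
        drive = max(0.0, delta_c)
    else:
        raise ValueError("sign_convention must be 'drop' or 'printed'")
    if drive > 0.0:
        # any detectable drop commands at least one native column: the
        # reorientation "cast" has a 45-deg floor (otherwise near-tangential
        # grazing orbits, where the per-step drop is second-order small,
        # are absorbing and the agent never climbs)
        cols = min(max(k_chemo * drive, 1.0), float(MAX_SHIFT_COLUMNS))
    else:
        cols = 0.0
    shift = cols * COLUMN_ANGLE
    if direction == "right":
        shift = -shift
    return copy_and_shift(current, shift)


def anemotaxis_heading(current, wind: WindSensorOutput) -> np.ndarray:
    """Desired heading of the anemotactic (ON-response) system: the upwind ring."""
    return upwind_ring(current, wind)


def random_heading(current_heading: float, rng: np.random.Generator, jitter: float = math.radians(30)) -> np.ndarray:
    """Correlated-random-walk desired heading: current heading plus uniform jitter."""
    if jitter <= 0:
        raise ValueError("jitter must be positive")
    return encode_heading(current_heading + rng.uniform(-jitter, jitter), 1.0)


@dataclass(frozen=True)
class PIMemory:
    """Path-integration state: the home vector (agent -> nest, world frame).

    The emitted ring points along the home vector with amplitude
    ``|home_vector| / reference_length`` clipped to [0, 1], so a
    full-vector ant weights PI maximally and the weight decays to zero on
    arrival.
    """

    home_vector: tuple[float, float]
    reference_length: float

    def __post_init__(self):
        if self.reference_length <= 0:
            raise ValueError("reference_length must be positive")

    @property
    def length(self) -> float:
        return math.hypot(*self.home_vector)

    @property
    def direction(self) -> float:
        return math.atan2(self.home_vector[1], self.home_vector[0])

    def ring(self) -> np.ndarray:
        amp = min(1.0, self.length / self.reference_length)
        if amp == 0.0:
            return np.zeros(8)
        return encode_heading(self.direction, amp)


def pi_update(memory: PIMemory, step_vector) -> PIMemory:
    """Decrement the home vector by the step displacement just taken."""
    sx, sy = step_vector
    hx, hy = memory.home_vector
    return replace(memory, home_vector=(hx - sx, hy - sy))


def integrate_pi_olfaction(
    pi_ring,
    mode: GuidanceMode,
    chemo_ring,
    anemo_ring,
    c: float,
    k_o: float,
    ra: RingAttractorParams | None = None,
    exploration_ring=None,
    k_explore: float = 0.5,
) -> np.ndarray:
    """Fuse PI with the mode-gated olfactory desired heading in the ring attractor.

    The PI ring enters as-is (amplitude already proportional to the
    remaining home-vector length); the olfactory ring — chemotaxis when
    OFF, anemotaxis when ON — is weighted by ``k_o * c`` (odour valence).
    In RANDOM mode (no reliable odour signal) the olfactory channel is
    silent; if an ``exploration_ring`` (a jittered copy of the current
    heading, see :func:`random_heading`) is supplied it enters with the
    small fixed weight ``k_explore``, so a strong home vector still
    dominates but a nearly-spent one lets the walk become exploratory
    search instead of a deterministic hover orbit.  The settled attractor
    bump decodes to the amplitude-weighted compromise direction.
    """
    if c < 0:
        raise ValueError("concentration must be non-negative")
    if mode is GuidanceMode.OFF:
        x2 = k_o * c * np.asarray(chemo_ring, dtype=float)
    elif mode is GuidanceMode.ON:
        x2 = k_o * c * np.asarray(anemo_ring, dtype=float)
    elif exploration_ring is not None:
        x2 = k_explore * np.asarray(exploration_ring, dtype=float)
    else:
        x2 = np.zeros(8)
    return ring_attractor_integrate([np.asarray(pi_ring, dtype=float), x2], ra)


def normalise_desired(ring, floor: float = 0.05) -> np.ndarray:
    """Re-encode a fused desired-heading bump at unit amplitude.

    Cue amplitudes decide the *direction* of the ring-attractor compromise;
    the motor command should not slow to a crawl just because the winning
    cue is weak (an ant with a nearly-spent home vector still walks
    briskly).  Returns a unit-amplitude bump in the ring's decoded
    direction, or the ring unchanged when its population vector is shorter
    than ``floor`` (no usable direction encoded).
    """
    from .rings import decode_ring

    theta, mag = decode_ring(ring)
    if mag <= floor:
        return np.asarray(ring, dtype=float).copy()
    return encode_heading(theta, 1.0)


def project_to_steering(integrated, current, k_motor: float = 1.0) -> SteeringOutput:
    """Feed the fused desired heading and the compass into the steering circuit."""
    return steer(integrated, current, k_motor)
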