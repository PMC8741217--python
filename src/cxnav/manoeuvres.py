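"""Frame-of-reference transfer manoeuvres.

Displaced ants recover by converting a transient egocentric cue into a
*geocentric* desired heading, stored as a working memory:

* **Wind compensation** — at the stereotyped "clutch" moment just before
  being blown away, the celestial-compass heading bump is copied and
  shifted by the egocentric upwind angle (from the wedge projection
  neurons).  The stored bump points upwind in world coordinates — back
  toward the route — and survives any displacement.
* **Backtracking** — on capture near the nest and release in unfamiliar
  terrain, the travel-heading bump is copied and shifted by a constant
  180 deg, sending the ant back the way it came.

Both triggers (clutch pose, visual-novelty drop) are experiment-script
events injected by the runner; the sensory computations behind them are
not modelled.  Once formed, a memory is immutable until cleared and is
the sole desired heading fed to steering while active.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .rings import SteeringOutput, WindSensorOutput, copy_and_shift, steer

__all__ = [
    "WorkingMemoryHeading",
    "form_wind_compensation_memory",
    "form_backtracking_memory",
    "navigate_from_memory",
]


@dataclass(frozen=True)
class WorkingMemoryHeading:
    """A stored desired-heading bump (geocentric, position-independent)."""

    ring: np.ndarray
    active: bool = True
    formed_at: int = 0

    def __post_init__(self):
        # freeze the stored bump so later navigation cannot mutate it
        r = np.array(self.ring, dtype=float, copy=True)
        r.setflags(write=False)
        object.__setattr__(self, "ring", r)


def form_wind_compensation_memory(
    compass, wind: WindSensorOutput, formed_at: int = 0
) -> WorkingMemoryHeading:
    """Store the geocentric upwind direction at the clutch instant."""
    return WorkingMemoryHeading(
        ring=copy_and_shift(compass, wind.egocentric_upwind_angle),
        formed_at=formed_at,
    )


def form_backtracking_memory(compass, formed_at: int = 0) -> WorkingMemoryHeading:
    """Store the capture-time travel heading shifted by a constant 180 deg."""
    return WorkingMemoryHeading(
        ring=copy_and_shift(compass, math.pi), formed_at=formed_at
    )


def navigate_from_memory(
    memory: WorkingMemoryHeading, compass, k_motor: float = 1.0
) -> SteeringOutput:
    """Steer toward the stored desired heading."""
    if not memory.active:
        raise ValueError("working-memory heading is not active")
    return steer(memory.ring, compass, k_motor)
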