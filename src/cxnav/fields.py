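"""Analytic odour landscapes and constant wind.

Two families of scalar concentration fields are provided, mirroring the
laboratory settings used in fly and ant olfactory-navigation experiments:

* :class:`GradientField` — windless, radially symmetric landscapes built
  from scaled exponentials.  The ``volcano`` variant peaks on a ring of
  radius ``r/2`` around the source; the ``linear`` variant keeps the same
  outer slope but dips only shallowly inside the rim.
* :class:`PlumeField` — a steady-state Gaussian plume carried by a constant
  wind.  Concentration is identically zero on the upwind side of the
  source and widens downwind with spread ``sigma = Ks * downwind_distance``.

All fields are deterministic, defined on the whole plane, and queried in
world coordinates (Cartesian, arena length units, angles in radians CCW
from +x).  Wind direction ``wind_dir`` is the direction the air flows
*toward*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GradientField",
    "PlumeField",
    "concentration_at",
    "plume_geometry",
    "sample_with_memory",
]

#: admissible plume-spread tuning factors (most stable .. least stable)
PLUME_KS_CHOICES = (0.5, 0.3, 0.2, 0.15, 0.1)


def _check_pos(pos) -> np.ndarray:
    p = np.asarray(pos, dtype=float)
    if p.shape != (2,) or not np.all(np.isfinite(p)):
        raise ValueError(f"position must be a finite 2-vector, got {pos!r}")
    return p


@dataclass(frozen=True)
class GradientField:
    """Windless radial odour landscape ('volcano' or 'linear').

    Parameters
    ----------
    kind
        ``"volcano"`` or ``"linear"``.
    k
        Peak concentration scale (a.u.), attained on the rim ``d = r/2``.
    tau
        Radial decay factor (1 / length unit).
    r
        Source radius; the concentration maximum sits on the circle of
        radius ``r/2`` about the source.
    source
        Source position in world coordinates.
    """

    kind: str = "volcano"
    k: float = 10.0
    tau: float = 0.1
    r: float = 6.0
    source: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.kind not in ("volcano", "linear"):
            raise ValueError(f"unknown gradient kind {self.kind!r}")
        if not (self.k > 0 and self.tau > 0 and self.r > 0):
            raise ValueError("k, tau and r must be positive")

    def concentration(self, pos) -> float:
        p = _check_pos(pos)
        d = float(np.hypot(*(p - np.asarray(self.source))))
        rim = self.r / 2.0
        if d > rim:
            return self.k * math.exp(self.tau * (rim - d))
        if self.kind == "volcano":
            return self.k * math.exp(self.tau * (d - rim))
        # linear: shallow dip toward the centre, clamped at zero
        return max(0.0, self.k - 0.2 * math.exp(self.tau * (d - rim)))


@dataclass(frozen=True)
class PlumeField:
    """Steady odour plume in a constant wind (zero on the upwind side).

    Two spread conventions are provided; both are mirror-symmetric about
    the plume centreline and exactly zero wherever the angle ``theta``
    between the source->point vector and the wind has ``cos(theta) <= 0``.

    ``spread="downwind"`` is the textbook steady-state Gaussian plume,
    widening with downwind distance:

        C = q / (u * sigma * sqrt(2 pi)) * exp(-cross^2 / (2 sigma^2)),
        sigma = ks * downwind_distance.

    ``spread="crosswind"`` evaluates both the spread and the exponent on
    the *crosswind* (projected) distance:

        C = q / (u * sigma * 2 pi) * exp(-cross^2 / (2 pi * sigma)),
        sigma = ks * cross,

    which collapses to a function of crosswind distance alone — an
    odour band of constant width running the whole downwind half-plane.
    This is the variant that makes a nest plume detectable along an
    entire homing route rather than only near the source.

    ``guard_radius`` caps the sigma->0 singularity: distances below it
    are evaluated on the guard circle (typically one agent step length).
    """

    q: float = 10.0
    wind_speed: float = 10.0
    wind_dir: float = -math.pi / 2
    ks: float = 0.2
    source: tuple[float, float] = (0.0, 0.0)
    guard_radius: float = 0.05
    spread: str = "downwind"

    def __post_init__(self):
        if not (self.q > 0 and self.wind_speed > 0 and self.ks > 0):
            raise ValueError("q, wind_speed and ks must be positive")
        if self.guard_radius <= 0:
            raise ValueError("guard_radius must be positive")
        if self.spread not in ("downwind", "crosswind"):
            raise ValueError(f"unknown spread convention {self.spread!r}")

    def geometry(self, pos) -> tuple[float, float, float]:
        """Angle off the plume axis and the cross/downwind distances.

        Returns ``(theta, crosswind_distance, downwind_distance)`` where
        ``theta`` in [0, pi] is the angle between the source->pos vector
        and the wind vector.  The source itself maps to ``(0, 0, 0)``.
        """
        p = _check_pos(pos)
        dx, dy = p - np.asarray(self.source)
        dist = math.hypot(dx, dy)
        if dist == 0.0:
            return 0.0, 0.0, 0.0
        wx, wy = math.cos(self.wind_dir), math.sin(self.wind_dir)
        cos_t = (dx * wx + dy * wy) / dist
        cos_t = min(1.0, max(-1.0, cos_t))
        theta = math.acos(cos_t)
        return theta, dist * math.sin(theta), dist * cos_t

    def concentration(self, pos) -> float:
        theta, cross, down = self.geometry(pos)
        if math.cos(theta) <= 0.0:
            return 0.0
        if self.spread == "downwind":
            down = max(down, self.guard_radius)
            sigma = self.ks * down
            return (
                self.q
                / (self.wind_speed * sigma * math.sqrt(2.0 * math.pi))
                * math.exp(-(cross * cross) / (2.0 * sigma * sigma))
            )
        cross = max(cross, self.guard_radius)
        sigma = self.ks * cross
        return (
            self.q
            / (self.wind_speed * sigma * 2.0 * math.pi)
            * math.exp(-(cross * cross) / (2.0 * math.pi * sigma))
        )


def concentration_at(fld, pos) -> float:
    """Odour concentration of ``fld`` (or a sequence of fields, summed)."""
    if isinstance(fld, (list, tuple)):
        return sum(f.concentration(pos) for f in fld)
    return fld.concentration(pos)


def plume_geometry(fld: PlumeField, pos):
    """See :meth:`PlumeField.geometry`."""
    return fld.geometry(pos)


def sample_with_memory(fld, pos, previous_concentration=None):
    """Sample ``fld`` at ``pos`` and report the one-step temporal change.

    Returns ``(C, deltaC)``; on the first sample (``previous_concentration``
    is None) the change is defined as zero.
    """
    c = concentration_at(fld, pos)
    if previous_concentration is None:
        return c, 0.0
    return c, c - float(previous_concentration)


def raster(fld, x_range, y_range, n=101):
    """Evaluate a field on a rectangular grid; returns (X, Y, C) arrays."""
    xs = np.linspace(*x_range, n)
    ys = np.linspace(*y_range, n)
    X, Y = np.meshgrid(xs, ys)
    C = np.empty_like(X)
    for i in range(X.shape[0]):
        for j in range(X.shape[1]):
            C[i, j] = concentration_at(fld, (X[i, j], Y[i, j]))
    return X, Y, C
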