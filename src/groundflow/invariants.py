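"""Ground optic-flow invariants for altitude control.

Two low-order variables (optical speed of the ground, splay angle of a
ground-parallel line) and their temporal derivatives, which are the
high-order invariants that specify a change of altitude:

* ``optical_speed`` / ``osrc`` — angular scrolling rate of the ground
  texture and its rate of change.
* ``splay_angle`` / ``sarc`` — vanishing-point angle of a ground line
  and its rate of change.

All angles are in radians; altitudes and lateral offsets in cm; speeds
in cm/s.  The relative-rate forms of both invariants reduce to
``-vz / z`` for an agent with constant forward speed and no lateral
motion relative to the splay line, which is what makes them
interchangeable error signals for a vertical-speed controller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "KinematicState",
    "OpticSample",
    "optical_speed",
    "osrc",
    "relative_osrc",
    "splay_angle",
    "sarc",
    "relative_sarc",
    "finite_difference_rates",
    "GroundContactError",
    "UndefinedRateError",
]

#: below this magnitude sin(2S) is treated as singular in relative_sarc
_SIN2S_EPS = 1e-9


class GroundContactError(ValueError):
    """Raised when an optical quantity is requested at altitude z <= 0."""


class UndefinedRateError(ZeroDivisionError):
    """Raised when a relative rate is requested at a singular operating point."""


@dataclass(frozen=True)
class KinematicState:
    """Instantaneous agent state in tunnel coordinates.

    ``x`` is longitudinal position, ``y`` the signed lateral offset from
    the tunnel midline, ``z`` altitude above the floor.  ``vx, vy, vz``
    are the matching velocity components and ``ax`` the forward
    acceleration (held at 0 for constant-speed traversals).
    """

    t: float
    x: float
    y: float
    z: float
    vx: float
    vy: float = 0.0
    vz: float = 0.0
    ax: float = 0.0


@dataclass(frozen=True)
class OpticSample:
    """Perceived optical variables at one instant.

    ``os_access`` is the accessibility coefficient of the ground's
    optical speed (1 = richly textured ground, near 0 = featureless),
    copied from the texture condition under which the sample was taken.
    """

    omega: float
    omega_dot: float
    splay: float
    splay_dot: float
    os_access: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.os_access <= 1.0:
            raise ValueError(f"os_access must be in [0, 1], got {self.os_access}")


def _require_airborne(z: float) -> None:
    if z <= 0:
        raise GroundContactError(f"altitude must be positive, got z={z}")


def optical_speed(vx: float, z: float) -> float:
    """Angular scrolling rate of the ground, ``vx / z`` (rad/s).

    Strictly decreasing in altitude for fixed forward speed: the closer
    the agent flies to the ground, the faster the ground sweeps its
    visual field.
    """
    _require_airborne(z)
    return vx / z


def osrc(vx: float, ax: float, z: float, vz: float) -> float:
    """Optical speed rate of change, ``d/dt (vx/z)`` (rad/s^2).

    Evaluates ``(z*ax - vx*vz) / z**2``.  For constant forward speed
    (``ax == 0``) its sign is opposite to the vertical speed: a loss of
    altitude always yields a positive rate.
    """
    _require_airborne(z)
    return (z * ax - vx * vz) / (z * z)


def relative_osrc(omega_dot: float, omega: float) -> float:
    """Relative optical speed rate of change, ``omega_dot / omega`` (1/s).

    For constant forward speed this equals ``-vz / z`` regardless of the
    (unknown) forward speed, which is what makes it an invariant.
    """
    if omega == 0:
        raise UndefinedRateError("relative OSRC undefined at omega == 0")
    return omega_dot / omega


def splay_angle(y_off: float, z: float) -> float:
    """Splay angle ``arctan(y_off / z)`` (rad) of a ground-parallel line.

    ``y_off`` is the lateral distance of the line from the agent's
    vertical projection; increasing in offset, decreasing in altitude.
    """
    _require_airborne(z)
    if y_off < 0:
        raise ValueError(f"lateral offset must be non-negative, got {y_off}")
    return math.atan2(y_off, z)


def sarc(S: float, vz: float, z: float, vy_rel: float = 0.0) -> float:
    """Splay angle rate of change (rad/s).

    ``(-vz/z) * cos(S) * sin(S) + (vy_rel/z) * cos(S)**2``, where
    ``vy_rel`` is the lateral speed of the splay line relative to the
    agent, so that a moving line stimulates the invariant even for a
    stationary agent.  A loss of altitude (vz < 0) increases the splay
    angle.
    """
    _require_airborne(z)
    c, s = math.cos(S), math.sin(S)
    return (-vz / z) * c * s + (vy_rel / z) * c * c


def relative_sarc(splay_dot: float, S: float) -> float:
    """Relative splay angle rate of change, ``2*splay_dot / sin(2S)`` (1/s).

    With no lateral motion relative to the line this equals ``-vz / z``,
    i.e. the same quantity as :func:`relative_osrc` — the two invariants
    share one right-hand side and can substitute for each other.
    """
    s2 = math.sin(2.0 * S)
    if abs(s2) < _SIN2S_EPS:
        raise UndefinedRateError(f"relative SARC undefined near S={S}")
    return 2.0 * splay_dot / s2


def finite_difference_rates(samples: np.ndarray, dt: float) -> np.ndarray:
    """Numerical time-derivative of a uniformly sampled series.

    Central differences on interior points, one-sided at the ends;
    output has the same length as the input.  Needs at least three
    samples and a positive step.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 1 or arr.size < 3:
        raise ValueError("need a 1-D series of at least 3 samples")
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    return np.gradient(arr, dt, edge_order=2)
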