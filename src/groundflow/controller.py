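"""Priority-based altitude controller and closed-loop tunnel flight.

The control law turns the two relative invariants into a vertical-speed
command.  When the ground's optical speed is easy to access, the
optical-speed rate is used exclusively; otherwise the two invariants
are blended, with the optical-speed term down-weighted by its
accessibility.  A perceived altitude *loss* (positive relative rate)
commands a climb.  With ``safety_mode`` on, descent commands that stem
from the splay-rate term alone are vetoed — descending toward the
ground on the word of a manipulable line is the unsafe choice — which
reproduces the asymmetric response to converging vs. diverging rods
over a weakly textured floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .invariants import KinematicState, OpticSample, _SIN2S_EPS
from .tunnel import (
    RodConfiguration,
    TextureCondition,
    TunnelGeometry,
    perceived_invariants,
)

__all__ = [
    "ControllerParams",
    "SimulationConfig",
    "Trajectory",
    "command_vertical_speed",
    "simulate_flight",
]

#: output sampling interval of recorded trajectories (s)
OUTPUT_DT = 0.01


@dataclass(frozen=True)
class ControllerParams:
    """Gains and priority settings of the altitude controller.

    ``k_gain`` maps the relative-rate error (1/s) to a vertical speed
    via multiplication by the current altitude.  ``c_star`` is the
    accessibility threshold above which the optical-speed rate is used
    exclusively.  ``w_osrc``/``w_sarc`` blend the two invariants below
    that threshold (the optical-speed weight is additionally scaled by
    the accessibility itself, and the pair renormalized).
    """

    k_gain: float = 0.8
    c_star: float = 0.5
    w_osrc: float = 0.5
    w_sarc: float = 0.5
    safety_mode: bool = True
    floor_margin: float = 2.0
    vz_max: float = 30.0

    def __post_init__(self) -> None:
        if self.k_gain <= 0:
            raise ValueError("k_gain must be positive")
        if not 0.0 <= self.c_star <= 1.0:
            raise ValueError("c_star must be in [0, 1]")
        if self.w_osrc < 0 or self.w_sarc < 0 or not math.isclose(self.w_osrc + self.w_sarc, 1.0):
            raise ValueError("w_osrc and w_sarc must be non-negative and sum to 1")
        if self.floor_margin < 0:
            raise ValueError("floor_margin must be non-negative")
        if self.vz_max <= 0:
            raise ValueError("vz_max must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """One simulated traversal of the tunnel."""

    geom: TunnelGeometry = field(default_factory=TunnelGeometry)
    rods: RodConfiguration = field(default_factory=RodConfiguration)
    texture: TextureCondition = field(default_factory=TextureCondition)
    dt: float = 0.01
    duration: float = 5.0
    forward_speed: float = 40.0
    entry_altitude: float = 14.0
    altitude_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")
        if self.forward_speed <= 0:
            raise ValueError("forward_speed must be positive")
        if not 0 < self.entry_altitude < self.geom.height:
            raise ValueError("entry_altitude must lie inside the tunnel")
        if self.altitude_noise_sd < 0:
            raise ValueError("altitude_noise_sd must be non-negative")
        n = round(OUTPUT_DT / self.dt)
        if n < 1 or abs(n * self.dt - OUTPUT_DT) > 1e-9:
            raise ValueError(f"dt must divide the {OUTPUT_DT} s output interval")


@dataclass(frozen=True)
class Trajectory:
    """A recorded flight: (t, x, z) samples at the output rate."""

    flight_id: str
    t: np.ndarray
    x: np.ndarray
    z: np.ndarray
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("t", "x", "z"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.t.shape == self.x.shape == self.z.shape) or self.t.ndim != 1:
            raise ValueError("t, x, z must be 1-D arrays of equal length")

    def __len__(self) -> int:
        return self.t.size


def _relative_rates(perceived: OpticSample) -> tuple[float, float]:
    """Relative rates of the two invariants; singular points read as 0."""
    rel_os = perceived.omega_dot / perceived.omega if perceived.omega != 0 else 0.0
    s2 = math.sin(2.0 * perceived.splay)
    rel_sp = 2.0 * perceived.splay_dot / s2 if abs(s2) >= _SIN2S_EPS else 0.0
    return rel_os, rel_sp


def command_vertical_speed(
    perceived: OpticSample, params: ControllerParams, z: float
) -> float:
    """Commanded vertical speed (cm/s) for one perceived sample.

    Error signal: the relative optical-speed rate alone when its
    accessibility is at least ``c_star``; otherwise the accessibility-
    scaled blend of both invariants.  The command is ``k_gain * e * z``
    (a positive error means the flow reads as sinking, so climb),
    subject to the safety veto and the floor margin, and clipped to
    ``±vz_max``.
    """
    if z <= 0:
        raise ValueError("altitude must be positive")
    rel_os, rel_sp = _relative_rates(perceived)
    c = perceived.os_access

    if c >= params.c_star:
        err = rel_os
    else:
        wo = params.w_osrc * c
        ws = params.w_sarc
        os_term = wo * rel_os
        sp_term = ws * rel_sp
        if params.safety_mode and sp_term < 0:
            sp_term = 0.0  # never descend on the splay rate's say-so
        err = (os_term + sp_term) / (wo + ws)

    cmd = params.k_gain * err * z
    if cmd < 0 and z < params.floor_margin:
        cmd = 0.0
    return float(np.clip(cmd, -params.vz_max, params.vz_max))


def simulate_flight(
    config: SimulationConfig,
    params: ControllerParams | None = None,
    flight_id: str = "flight",
) -> Trajectory:
    """Integrate one closed-loop traversal and record it at 100 Hz.

    Forward position advances at the constant configured speed; the
    vertical speed is the controller command computed from the optic
    sample of the previous step's achieved motion, plus optional white
    process noise scaled by sqrt(dt).  Altitude is confined to the
    tunnel.  The flight ends at the exit wall or at ``duration``,
    whichever comes first; samples are decimated to the 100 Hz output
    grid.  Deterministic for a fixed seed.
    """
    params = params or ControllerParams()
    geom = config.geom
    rng = np.random.default_rng(config.seed)
    dt = config.dt
    n_steps = int(round(config.duration / dt))
    stride = round(OUTPUT_DT / dt)

    z_lo, z_hi = 1e-3, geom.height - 1e-3
    t = 0.0
    x = 0.0
    z = float(config.entry_altitude)
    # The loop closes on the *commanded* vertical speed (efference copy):
    # unmodelled jitter is treated as unperceived disturbance, so the
    # safety veto's asymmetry cannot rectify symmetric noise into drift.
    vz = 0.0

    ts = [t]
    xs = [x]
    zs = [z]
    for i in range(n_steps):
        state = KinematicState(t=t, x=x, y=0.0, z=z, vx=config.forward_speed, vz=vz)
        perceived = perceived_invariants(state, config.rods, config.texture, geom, t)
        cmd = command_vertical_speed(perceived, params, z)

        dz = cmd * dt
        if config.altitude_noise_sd > 0:
            dz += config.altitude_noise_sd * math.sqrt(dt) * rng.standard_normal()
        z_new = float(np.clip(z + dz, z_lo, z_hi))
        vz = cmd if z_lo < z_new < z_hi else (z_new - z) / dt
        z = z_new
        t = (i + 1) * dt  # exact grid, no accumulated float error
        x = config.forward_speed * t

        if (i + 1) % stride == 0:
            ts.append((i + 1) // stride * OUTPUT_DT)
            xs.append(x)
            zs.append(z)
        if x >= geom.length:
            break

    condition = {
        "rod_mode": config.rods.mode,
        "texture": config.texture.kind,
        "onset": config.rods.onset,
        "forward_speed": config.forward_speed,
        "seed": config.seed,
    }
    return Trajectory(flight_id=flight_id, t=np.array(ts), x=np.array(xs), z=np.array(zs), condition=condition)
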