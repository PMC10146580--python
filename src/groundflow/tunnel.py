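"""Flight tunnel, ground textures and motorized splay-line rods.

The tunnel carries two manipulanda:

* reversible floor sheets that make the ground's optical speed easy
  (high-contrast stripes) or hard (matt white) to access — modelled as
  an accessibility coefficient, never as a change to the geometric
  optic-flow values;
* a pair of rods running the length of the tunnel at the floor–wall
  junction that can be moved laterally, either between flights (static
  splay-angle manipulation) or during flight (dynamic splay-rate
  stimulation).

Rod convergence is stipulated to produce a *positive* perceived splay
rate (and divergence a negative one), matching the stimulation the
physical device delivers; see the note in :func:`perceived_invariants`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .invariants import (
    KinematicState,
    OpticSample,
    optical_speed,
    osrc,
    sarc,
    splay_angle,
)

__all__ = [
    "TunnelGeometry",
    "RodConfiguration",
    "TextureCondition",
    "ROD_MODES",
    "STATIC_MODES",
    "DYNAMIC_MODES",
    "rod_offset",
    "rod_offset_rate",
    "perceived_invariants",
    "condition_from_dict",
    "load_condition",
]

ROD_MODES = (
    "parallel",
    "narrow",
    "static_converging",
    "static_diverging",
    "dynamic_converging",
    "dynamic_diverging",
)
STATIC_MODES = ("parallel", "narrow", "static_converging", "static_diverging")
DYNAMIC_MODES = ("dynamic_converging", "dynamic_diverging")

#: rods never approach the midline closer than this (cm)
ROD_MIN_OFFSET = 0.5

#: default accessibility of ground optical speed per floor texture
TEXTURE_ACCESS = {"striped": 1.0, "white": 0.1}


@dataclass(frozen=True)
class TunnelGeometry:
    """Tunnel dimensions in cm; entrance hole is on the short end wall."""

    length: float = 220.0
    height: float = 71.0
    width: float = 25.0
    entrance_height: float = 14.0

    def __post_init__(self) -> None:
        if min(self.length, self.height, self.width, self.entrance_height) <= 0:
            raise ValueError("all tunnel dimensions must be positive")
        if self.entrance_height >= self.height:
            raise ValueError("entrance must sit below the ceiling")

    @property
    def half_width(self) -> float:
        return self.width / 2.0


@dataclass(frozen=True)
class RodConfiguration:
    """State of the motorized rods for one condition.

    ``onset`` is the time after tunnel entry at which dynamic motion
    starts; ``rate`` the lateral speed of each rod base; and
    ``static_offset`` the fixed base offset used by the narrow and
    static converging/diverging modes.
    """

    mode: str = "parallel"
    onset: float = 2.0
    rate: float = 1.5
    static_offset: float = 8.5

    def __post_init__(self) -> None:
        if self.mode not in ROD_MODES:
            raise ValueError(f"unknown rod mode {self.mode!r}; expected one of {ROD_MODES}")
        if self.onset < 0:
            raise ValueError("onset must be non-negative")
        if self.mode in DYNAMIC_MODES and self.rate <= 0:
            raise ValueError("dynamic rod modes need a positive rate")
        if self.static_offset < 0:
            raise ValueError("static_offset must be non-negative")

    @property
    def is_dynamic(self) -> bool:
        return self.mode in DYNAMIC_MODES


@dataclass(frozen=True)
class TextureCondition:
    """Floor texture and the resulting accessibility of optical speed."""

    kind: str = "striped"
    os_access: float = field(default=-1.0)

    def __post_init__(self) -> None:
        if self.kind not in TEXTURE_ACCESS:
            raise ValueError(f"texture kind must be one of {tuple(TEXTURE_ACCESS)}")
        if self.os_access < 0:  # sentinel: take the per-kind default
            object.__setattr__(self, "os_access", TEXTURE_ACCESS[self.kind])
        if not 0.0 <= self.os_access <= 1.0:
            raise ValueError(f"os_access must be in [0, 1], got {self.os_access}")


def rod_offset(t: float, cfg: RodConfiguration, geom: TunnelGeometry | None = None) -> float:
    """Lateral offset of a rod base from the midline at time ``t`` (cm).

    Parallel rods sit at the wall (half width); narrow/static modes at
    ``static_offset``; dynamic modes start at the wall and translate at
    ``rate`` from ``onset`` on.  Converging motion is clamped at
    ``ROD_MIN_OFFSET``; diverging motion is unbounded above (the rods
    ride up the side walls, which keeps stimulating the splay line).
    """
    if t < 0:
        raise ValueError("time since entry must be non-negative")
    geom = geom or TunnelGeometry()
    half = geom.half_width
    if cfg.mode == "parallel":
        return half
    if cfg.mode in ("narrow", "static_converging", "static_diverging"):
        return min(cfg.static_offset, half)
    travel = cfg.rate * max(0.0, t - cfg.onset)
    if cfg.mode == "dynamic_converging":
        return max(ROD_MIN_OFFSET, half - travel)
    return half + travel  # dynamic_diverging


def rod_offset_rate(t: float, cfg: RodConfiguration, geom: TunnelGeometry | None = None) -> float:
    """Signed lateral speed of the rod base at time ``t`` (cm/s)."""
    geom = geom or TunnelGeometry()
    if not cfg.is_dynamic or t < cfg.onset:
        return 0.0
    if cfg.mode == "dynamic_converging":
        if rod_offset(t, cfg, geom) <= ROD_MIN_OFFSET:
            return 0.0
        return -cfg.rate
    return cfg.rate


def perceived_invariants(
    state: KinematicState,
    cfg: RodConfiguration,
    tex: TextureCondition,
    geom: TunnelGeometry | None = None,
    t: float | None = None,
) -> OpticSample:
    """Optical variables an agent in ``state`` perceives under a condition.

    Optical speed and its rate come from the ground texture; splay angle
    and rate from the rod nearer to the agent.  The texture condition
    contributes only the accessibility coefficient.

    Sign convention for rod motion: the device is built so that
    convergence stimulates a *rising* splay angle (signalling altitude
    loss) and divergence a falling one.  Under the plain arctan
    geometry an inward-moving line would do the opposite, so the
    rod-motion term enters with its sign flipped; the altitude term is
    untouched.
    """
    geom = geom or TunnelGeometry()
    if t is None:
        t = state.t
    if abs(state.y) > geom.half_width:
        raise ValueError("agent is outside the tunnel laterally")

    om = optical_speed(state.vx, state.z)
    om_dot = osrc(state.vx, state.ax, state.z, state.vz)

    offset = rod_offset(t, cfg, geom)
    # nearer rod: base offset minus the agent's displacement toward it
    y_off = max(0.0, offset - abs(state.y))
    S = splay_angle(y_off, state.z)
    # stipulated sign: converging rods (offset rate < 0) must raise S
    vy_rel = -rod_offset_rate(t, cfg, geom) - state.vy
    S_dot = sarc(S, state.vz, state.z, vy_rel)

    return OpticSample(
        omega=om,
        omega_dot=om_dot,
        splay=S,
        splay_dot=S_dot,
        os_access=tex.os_access,
    )


def condition_from_dict(spec: dict) -> tuple[TunnelGeometry, RodConfiguration, TextureCondition]:
    """Build (geometry, rods, texture) from a plain mapping.

    Recognised keys: ``geometry`` (field overrides), ``rods`` (mode /
    onset / rate / static_offset) and ``texture`` (kind, optional
    os_access override).  Unknown keys raise.
    """
    known = {"geometry", "rods", "texture"}
    extra = set(spec) - known
    if extra:
        raise ValueError(f"unknown condition keys: {sorted(extra)}")
    geom = TunnelGeometry(**spec.get("geometry", {}))
    rods = RodConfiguration(**spec.get("rods", {}))
    tex_spec = dict(spec.get("texture", {}))
    tex = TextureCondition(**tex_spec)
    return geom, rods, tex


def load_condition(path: str | Path) -> tuple[TunnelGeometry, RodConfiguration, TextureCondition]:
    """Read a condition specification from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        spec = json.loads(text)
    else:
        spec = yaml.safe_load(text)
    if not isinstance(spec, dict):
        raise ValueError(f"{path} does not contain a mapping")
    return condition_from_dict(spec)
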