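"""Synthetic flight cohorts and their on-disk representation.

A cohort emulates the structure of tracked tunnel flights: per-flight
constant forward speed drawn from a truncated normal, entry near the
14 cm entrance hole, controller-driven altitude responses to the rod
condition, 100 Hz sampling, white tracking jitter and optional
pixel-quantization of the recorded altitude.

Each flight is written as a plain CSV (``t_s,x_cm,z_cm``, one row per
10 ms sample) with a JSON sidecar carrying the flight id, condition and
generator parameters.  Seeding is hierarchical: the master seed and the
flight index are combined into a per-flight child seed, so enlarging a
cohort never reshuffles the flights already generated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .controller import (
    OUTPUT_DT,
    ControllerParams,
    SimulationConfig,
    Trajectory,
    simulate_flight,
)
from .tunnel import ROD_MODES, RodConfiguration, TextureCondition, TunnelGeometry

__all__ = [
    "CohortSpec",
    "PIXEL_QUANTUM_CM",
    "generate_cohort",
    "write_flights",
    "read_flights",
]

#: vertical extent of one tracking pixel (71 cm / 210 px)
PIXEL_QUANTUM_CM = 71.0 / 210.0


@dataclass(frozen=True)
class CohortSpec:
    """Generator settings for one batch of synthetic flights.

    ``conditions`` lists (rod_mode, texture) cells; every cell gets
    ``n_flights`` flights.  Forward speed is drawn once per flight from
    a normal truncated to ``speed_bounds``; ``tracking_noise_sd`` is
    white per-sample measurement jitter on the recorded altitude, on
    top of the process noise the simulator integrates.
    """

    n_flights: int = 10
    conditions: tuple = (("parallel", "white"),)
    speed_mean: float = 40.0
    speed_sd: float = 5.0
    speed_bounds: tuple = (20.0, 60.0)
    entry_altitude: float = 14.0
    entry_jitter_sd: float = 0.5
    altitude_noise_sd: float = 0.05
    tracking_noise_sd: float = 0.1
    pixel_quantization: bool = False
    duration: float = 5.0
    onset: float = 2.0
    rod_rate: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_flights < 2:
            raise ValueError("need at least 2 flights per condition")
        for sd in (self.speed_sd, self.entry_jitter_sd, self.altitude_noise_sd, self.tracking_noise_sd):
            if sd < 0:
                raise ValueError("standard deviations must be non-negative")
        for mode, tex in self.conditions:
            if mode not in ROD_MODES:
                raise ValueError(f"unknown rod mode {mode!r}")
            if tex not in ("striped", "white"):
                raise ValueError(f"unknown texture {tex!r}")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, bounds: tuple) -> float:
    lo, hi = bounds
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(mean, lo, hi))


def _child_seed(master: int, index: int) -> np.random.SeedSequence:
    # counter-based split: flight i's stream depends only on (master, i)
    return np.random.SeedSequence(entropy=(int(master), int(index)))


def generate_cohort(
    spec: CohortSpec,
    params: ControllerParams | None = None,
    geom: TunnelGeometry | None = None,
) -> list[Trajectory]:
    """Simulate every flight of a cohort, reproducibly under the master seed."""
    params = params or ControllerParams()
    geom = geom or TunnelGeometry()
    flights: list[Trajectory] = []
    index = 0
    for mode, tex_kind in spec.conditions:
        for rep in range(spec.n_flights):
            ss = _child_seed(spec.seed, index)
            rng = np.random.default_rng(ss)
            speed = _truncated_normal(rng, spec.speed_mean, spec.speed_sd, spec.speed_bounds)
            entry = spec.entry_altitude + spec.entry_jitter_sd * rng.standard_normal()
            entry = float(np.clip(entry, 2.0, geom.height - 2.0))
            sim_seed = int(rng.integers(2**31))
            config = SimulationConfig(
                geom=geom,
                rods=RodConfiguration(mode=mode, onset=spec.onset, rate=spec.rod_rate),
                texture=TextureCondition(kind=tex_kind),
                duration=spec.duration,
                forward_speed=speed,
                entry_altitude=entry,
                altitude_noise_sd=spec.altitude_noise_sd,
                seed=sim_seed,
            )
            fid = f"{mode}-{tex_kind}-{rep:03d}"
            traj = simulate_flight(config, params, flight_id=fid)
            z = traj.z.copy()
            if spec.tracking_noise_sd > 0:
                z = z + spec.tracking_noise_sd * rng.standard_normal(z.size)
            if spec.pixel_quantization:
                z = np.round(z / PIXEL_QUANTUM_CM) * PIXEL_QUANTUM_CM
            z = np.clip(z, 1e-3, geom.height - 1e-3)
            flights.append(
                Trajectory(
                    flight_id=fid,
                    t=traj.t,
                    x=traj.x,
                    z=z,
                    condition=dict(traj.condition, experiment_cell=f"{mode}/{tex_kind}"),
                )
            )
            index += 1
    return flights


def write_flights(flights: list[Trajectory], path: str | Path) -> list[Path]:
    """Write one CSV plus one JSON sidecar per flight under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []
    for traj in flights:
        stem = path / traj.flight_id
        df = pd.DataFrame({"t_s": traj.t, "x_cm": traj.x, "z_cm": traj.z})
        df.to_csv(stem.with_suffix(".csv"), index=False, float_format="%.4f")
        meta = {"flight_id": traj.flight_id, **traj.condition}
        stem.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))
        written.append(stem.with_suffix(".csv"))
    return written


def _parse_flight_csv(csv_path: Path) -> pd.DataFrame:
    df = pd.read_csv(csv_path)
    required = ["t_s", "x_cm", "z_cm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{csv_path}: missing columns {missing}")
    if len(df) == 0:
        raise ValueError(f"{csv_path}: empty flight file")
    t = df["t_s"].to_numpy(dtype=float)
    steps = np.diff(t)
    bad = np.flatnonzero(np.abs(steps - OUTPUT_DT) > 1e-6)
    if bad.size:
        # +2: one for the header line, one for 0- vs 1-based counting
        raise ValueError(
            f"{csv_path}: non-uniform or non-monotone time at line {int(bad[0]) + 2}"
        )
    if abs(t[0]) > 1e-9:
        raise ValueError(f"{csv_path}: time must start at 0")
    return df


def read_flights(path: str | Path) -> list[Trajectory]:
    """Read every flight CSV (with optional sidecar) under ``path``."""
    path = Path(path)
    csvs = sorted(path.glob("*.csv")) if path.is_dir() else [path]
    if not csvs:
        raise FileNotFoundError(f"no flight CSVs under {path}")
    flights = []
    for csv_path in csvs:
        df = _parse_flight_csv(csv_path)
        sidecar = csv_path.with_suffix(".json")
        condition = {}
        flight_id = csv_path.stem
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            flight_id = meta.pop("flight_id", flight_id)
            condition = meta
        flights.append(
            Trajectory(
                flight_id=flight_id,
                t=df["t_s"].to_numpy(float),
                x=df["x_cm"].to_numpy(float),
                z=df["z_cm"].to_numpy(float),
                condition=condition,
            )
        )
    return flights
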