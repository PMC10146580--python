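"""Trajectory post-processing: calibration, median binning, epoching.

Raw flights are (t, x, z) series at 100 Hz.  The pipeline maps pixel
tracking output to cm (linear calibration of the cropped video frame),
reduces each flight to 150 ms median altitude bins, screens flights
with a ground-following criterion, and assembles the flights-by-bins
matrices the nonparametric tests consume.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .controller import OUTPUT_DT, Trajectory

__all__ = [
    "FrameSpec",
    "BinnedAltitude",
    "EpochMatrix",
    "calibrate",
    "horizontal_fov_degrees",
    "bin_median",
    "ground_following_filter",
    "epoch_split",
    "samples_per_bin",
    "BIN_WIDTH_S",
]

log = logging.getLogger(__name__)

#: width of one median bin (s)
BIN_WIDTH_S = 0.15


@dataclass(frozen=True)
class FrameSpec:
    """Cropped video frame and the physical extent it images.

    Row 0 is the tunnel top; the full crop height spans the full tunnel
    height and the crop width spans the imaged floor section.
    """

    width_px: int = 620
    height_px: int = 210
    width_cm: float = 160.0
    height_cm: float = 71.0
    camera_distance_cm: float = 165.0

    @property
    def cm_per_px_x(self) -> float:
        return self.width_cm / self.width_px

    @property
    def cm_per_px_z(self) -> float:
        return self.height_cm / self.height_px

    @property
    def mm_per_px_vertical(self) -> float:
        """Vertical physical extent of one pixel, in mm."""
        return 10.0 * self.cm_per_px_z


def calibrate(cols, rows, frame: FrameSpec | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Map pixel (column, row) tracking output to (x, z) in cm.

    Linear in both axes; row 0 is the tunnel top, so z decreases with
    row index.  Coordinates outside the frame are rejected.
    """
    frame = frame or FrameSpec()
    cols = np.asarray(cols, dtype=float)
    rows = np.asarray(rows, dtype=float)
    if np.any((cols < 0) | (cols >= frame.width_px)):
        raise ValueError("column index outside the cropped frame")
    if np.any((rows < 0) | (rows >= frame.height_px)):
        raise ValueError("row index outside the cropped frame")
    x = cols * frame.cm_per_px_x
    z = frame.height_cm - rows * frame.cm_per_px_z
    return x, z


def horizontal_fov_degrees(frame: FrameSpec | None = None) -> float:
    """Full horizontal viewing angle of the imaged plane, in degrees."""
    frame = frame or FrameSpec()
    return math.degrees(2.0 * math.atan2(frame.width_cm / 2.0, frame.camera_distance_cm))


@dataclass(frozen=True)
class BinnedAltitude:
    """Median altitude of one flight in consecutive 150 ms bins."""

    flight_id: str
    bin_centers: np.ndarray
    median_altitude: np.ndarray
    bin_width: float = BIN_WIDTH_S
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_centers", np.asarray(self.bin_centers, dtype=float))
        object.__setattr__(self, "median_altitude", np.asarray(self.median_altitude, dtype=float))
        if self.bin_centers.shape != self.median_altitude.shape:
            raise ValueError("bin_centers and median_altitude must align")


def samples_per_bin(sample_dt: float = OUTPUT_DT, bin_width: float = BIN_WIDTH_S) -> int:
    """Number of raw samples aggregated into one median bin."""
    n = round(bin_width / sample_dt)
    if abs(n * sample_dt - bin_width) > 1e-9 or n < 1:
        raise ValueError("bin width must be an integer multiple of the sample step")
    return n


def bin_median(traj: Trajectory, bin_width: float = BIN_WIDTH_S) -> BinnedAltitude:
    """Reduce a flight to per-bin median altitudes.

    Bins are aligned to the first sample (tunnel entry), consecutive and
    non-overlapping; a trailing remainder shorter than one bin is
    dropped.  Fewer samples than one full bin is an error.
    """
    dts = np.diff(traj.t)
    if dts.size and not np.allclose(dts, dts[0], atol=1e-9):
        raise ValueError("trajectory must be uniformly sampled")
    dt = float(dts[0]) if dts.size else OUTPUT_DT
    n = samples_per_bin(dt, bin_width)
    n_bins = len(traj) // n
    if n_bins < 1:
        raise ValueError(f"need at least {n} samples, got {len(traj)}")
    z = traj.z[: n_bins * n].reshape(n_bins, n)
    medians = np.median(z, axis=1)
    centers = traj.t[0] + (np.arange(n_bins) + 0.5) * bin_width
    return BinnedAltitude(
        flight_id=traj.flight_id,
        bin_centers=centers,
        median_altitude=medians,
        bin_width=bin_width,
        condition=dict(traj.condition),
    )


def ground_following_filter(
    traj: Trajectory,
    max_median_altitude: float = 35.5,
    ceiling_clearance: float = 0.5,
    tunnel_height: float = 71.0,
) -> bool:
    """Keep flights that actually follow the ground.

    Default criterion (this pipeline's choice — the behavioural
    criterion is not standardized): median altitude below half the
    tunnel height and no sample within ``ceiling_clearance`` of the
    ceiling.  Thresholds are configurable.
    """
    if np.median(traj.z) >= max_median_altitude:
        return False
    if np.any(traj.z > tunnel_height - ceiling_clearance):
        return False
    return True


@dataclass(frozen=True)
class EpochMatrix:
    """Flights-by-bins altitude matrix around a perturbation onset."""

    values: np.ndarray  # (n_flights, n_bins)
    bin_centers: np.ndarray
    flight_ids: tuple
    onset: float
    n_before: int
    n_after: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "bin_centers", np.asarray(self.bin_centers, dtype=float))
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[0] < 2 or self.values.shape[1] < 2:
            raise ValueError("need at least 2 flights and 2 bins")
        if self.values.shape[1] != self.bin_centers.size:
            raise ValueError("column count must match bin_centers")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("missing cells are not allowed")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=list(self.flight_ids),
            columns=[f"{c:.3f}" for c in self.bin_centers],
        )


def epoch_split(
    binned: list[BinnedAltitude],
    onset: float = 2.0,
    n_before: int = 3,
    n_after: int = 3,
    grid: np.ndarray | None = None,
) -> EpochMatrix:
    """Assemble the flights-by-bins matrix around the perturbation onset.

    Columns are the ``n_before`` bins whose centers precede the onset
    and the ``n_after`` bins whose centers follow it.  If ``grid`` is
    given (e.g. a 0.25 s grid from 1.25 to 3 s), columns are instead the
    bins whose centers are nearest each grid time.  Flights that do not
    cover the requested columns are dropped with a warning.
    """
    if not binned:
        raise ValueError("no binned flights supplied")

    rows = []
    ids = []
    centers_out = None
    for b in binned:
        if grid is not None:
            target = np.asarray(grid, dtype=float)
            idx = np.array([int(np.argmin(np.abs(b.bin_centers - g))) for g in target])
            covered = np.all(np.abs(b.bin_centers[idx] - target) <= b.bin_width)
        else:
            before = np.flatnonzero(b.bin_centers < onset)[-n_before:] if np.any(b.bin_centers < onset) else np.array([], dtype=int)
            after = np.flatnonzero(b.bin_centers > onset)[:n_after]
            idx = np.concatenate([before, after])
            covered = before.size == n_before and after.size == n_after
        if not covered:
            log.warning("flight %s does not cover the epoch window; dropped", b.flight_id)
            continue
        if centers_out is None:
            centers_out = b.bin_centers[idx]
        rows.append(b.median_altitude[idx])
        ids.append(b.flight_id)

    if len(rows) < 2:
        raise ValueError("fewer than 2 flights cover the epoch window")
    return EpochMatrix(
        values=np.vstack(rows),
        bin_centers=centers_out,
        flight_ids=tuple(ids),
        onset=onset,
        n_before=n_before,
        n_after=n_after,
    )
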