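"""Core physical data containers.

Everything downstream of the file readers works in physical units: nanometres
for geometry, minutes/hours for time, picoamps/millivolts/picosiemens for
electrophysiology.  Arrays are indexed 0-based and pixel/voxel *centres* sit
at ``(i + 0.5) * pixel_size``; no routine ever reports a quantity in pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "HeightMapSeries",
    "DensityField",
    "FilamentPath",
    "CrossProfile",
    "RingGeometry",
    "LengthPopulation",
    "KineticCurve",
    "CurrentTrace",
]


class CalibrationError(ValueError):
    """Raised when physical calibration metadata is missing or invalid."""


@dataclass
class HeightMapSeries:
    """Time-stamped stack of AFM height maps with physical calibration.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, ny, nx)``, heights in nm.
    pixel_size
        Lateral pixel size in nm.
    frame_interval
        Nominal time between frames in minutes.
    timestamps
        Acquisition time of each frame in minutes; defaults to
        ``frame_interval * arange(n_frames)``.
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    timestamps: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, ny, nx) stack")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("heights must be finite")
        if self.pixel_size <= 0:
            raise CalibrationError("pixel_size must be positive (nm)")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive (min)")
        if self.timestamps is None:
            self.timestamps = self.frame_interval * np.arange(len(self.frames))
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if len(self.timestamps) != len(self.frames):
            raise ValueError("one timestamp per frame required")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class DensityField:
    """2D image or 3D volume of grayscale density with voxel calibration."""

    grid: np.ndarray
    voxel_size: float
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim not in (2, 3):
            raise ValueError("grid must be 2D or 3D")
        if self.voxel_size <= 0:
            raise CalibrationError("voxel_size must be positive (nm)")

    @property
    def rank(self) -> int:
        return self.grid.ndim


@dataclass
class FilamentPath:
    """Ordered polyline through a traced assembly, coordinates in nm.

    Point ordering is stable: the lexicographically smaller endpoint comes
    first.  ``border`` marks objects touching the field edge (length is
    censored there); ``branched`` marks skeletons with more than two tips,
    of which the longest geodesic path was kept.
    """

    points: np.ndarray
    border: bool = False
    branched: bool = False

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if len(self.points) < 2:
            raise ValueError("a path needs at least two points")
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(steps == 0):
            raise ValueError("duplicated consecutive points")

    @property
    def end_a(self) -> np.ndarray:
        return self.points[0]

    @property
    def end_b(self) -> np.ndarray:
        return self.points[-1]

    @property
    def arc_length(self) -> np.ndarray:
        """Cumulative arc length at each point, starting at 0."""
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])

    def canonical(self) -> "FilamentPath":
        """Return the path ordered with the lexicographically smaller endpoint first."""
        a, b = tuple(self.points[0]), tuple(self.points[-1])
        if b < a:
            return FilamentPath(self.points[::-1].copy(), self.border, self.branched)
        return self


@dataclass
class CrossProfile:
    """1D profile perpendicular to a filament's long axis.

    ``offsets`` are signed distances (nm) from the path point; ``baseline``
    is estimated from the outer quartiles of the window.
    """

    offsets: np.ndarray
    values: np.ndarray
    baseline: float
    threshold_fraction: float = 0.15

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.offsets) <= 0):
            raise ValueError("offsets must be strictly increasing")
        if not np.isfinite(self.baseline):
            raise ValueError("baseline must be finite")
        if not 0 < self.threshold_fraction < 1:
            raise ValueError("threshold_fraction must be in (0, 1)")


@dataclass
class RingGeometry:
    """Measured annulus geometry (nm)."""

    outer_diameter: float
    inner_diameter: float
    channel_length: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 < self.inner_diameter < self.outer_diameter:
            raise ValueError("require 0 < inner_diameter < outer_diameter")


@dataclass
class LengthPopulation:
    """Lengths of particles measured at one time point."""

    lengths: np.ndarray
    t_label: Optional[float] = None

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        if np.any(self.lengths <= 0):
            raise ValueError("lengths must be positive")


@dataclass
class KineticCurve:
    """Fluorescence kinetic trace (ThT or Fluo-4), time in hours by default."""

    t: np.ndarray
    f: np.ndarray
    time_unit: str = "h"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.f)):
            raise ValueError("fluorescence must be finite")


@dataclass
class CurrentTrace:
    """Voltage-clamp current trace under a step-voltage protocol."""

    t: np.ndarray          # ms
    i: np.ndarray          # pA
    v: np.ndarray          # mV, per sample
    sampling_rate: float   # Hz
    filter_cutoff: Optional[float] = None  # Hz, of the acquisition low-pass

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.i = np.asarray(self.i, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if not (len(self.t) == len(self.i) == len(self.v)):
            raise ValueError("t, i, v must be equally long")
        if self.sampling_rate <= 0:
            raise CalibrationError("sampling_rate must be positive (Hz)")
        if np.any(np.abs(self.v) > 200):
            raise ValueError("|v| must be <= 200 mV")

    @property
    def duration_ms(self) -> float:
        return len(self.t) / self.sampling_rate * 1000.0
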