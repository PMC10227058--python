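"""Shared data containers and file I/O for the awake-mouse retinal imaging pipeline.

All imaging stages operate on a small set of in-memory containers:
:class:`VideoFrames` for frame stacks (pupil camera, SLO, AOSLO),
:class:`SpaceTimeImage` for repeated 1-D line scans across a vessel, and
:class:`ScaleModel` for retinal angular/metric unit conversion.

Conventions used throughout the package:

* pixel indexing is 0-based, row-major, origin at the top-left;
* displacements are reported as ``(dx, dy)`` = (columns, rows), positive
  right/down;
* intensities are min-max normalized to [0, 1] per video at load time so
  that intensity-ratio rules (e.g. the 60 %-of-mean blink rule) are well
  defined;
* timestamps are seconds as floats.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "VideoFrames",
    "SpaceTimeImage",
    "ScaleModel",
    "normalize_intensity",
    "read_video",
    "write_trace",
    "read_trace",
    "get_logger",
]

#: Microns of retina per degree of visual angle in the mouse eye, used to
#: report motion amplitudes interchangeably in µm and arc minutes
#: (5.95 µm <-> 10.50 arcmin implies ~34 µm/deg).
DEFAULT_MICRONS_PER_DEGREE = 34.0


def get_logger(name: str = "awakeretina") -> logging.Logger:
    """Package logger writing to standard error."""
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s: %(message)s")
        )
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


def normalize_intensity(frames: np.ndarray) -> np.ndarray:
    """Min-max normalize an intensity array to [0, 1].

    Normalization is global (per video, not per frame) so that relative
    frame brightness — the quantity the blink detector thresholds — is
    preserved.  A constant array maps to all zeros.  Idempotent on data
    already spanning [0, 1].
    """
    frames = np.asarray(frames, dtype=np.float64)
    lo = float(frames.min())
    hi = float(frames.max())
    if hi - lo <= 0:
        return np.zeros_like(frames)
    return (frames - lo) / (hi - lo)


@dataclass
class VideoFrames:
    """A timestamped stack of intensity frames.

    Parameters
    ----------
    frames
        3-D array, ``(time, rows, cols)``, values in [0, 1].
    frame_rate
        Frames per second (e.g. 8.8 for the SLO pupil stream).
    timestamps
        Seconds per frame, strictly increasing.  Acquisition gaps are
        represented as timestamp jumps, never as filler frames.
    pixel_scale
        Physical units per pixel.
    scale_units
        Units tag for ``pixel_scale`` (``"um/px"``, ``"deg/px"``,
        ``"mm/px"``).
    """

    frames: np.ndarray
    frame_rate: float
    timestamps: np.ndarray | None = None
    pixel_scale: float = 1.0
    scale_units: str = "px"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D (time, rows, cols) array")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.timestamps is None:
            self.timestamps = np.arange(self.n_frames) / self.frame_rate
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        if self.timestamps.shape != (self.n_frames,):
            raise ValueError("timestamps must have one entry per frame")
        if self.n_frames > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.frames.size and (
            self.frames.min() < -1e-12 or self.frames.max() > 1 + 1e-12
        ):
            raise ValueError("frame intensities must lie in [0, 1]; normalize first")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration(self) -> float:
        """Nominal duration in seconds (last timestamp + one frame period)."""
        return float(self.timestamps[-1]) + 1.0 / self.frame_rate


@dataclass
class SpaceTimeImage:
    """Space-time record of a repeated 1-D line scan across a blood vessel.

    Rows are scan lines (time), columns are positions along the scan
    (space).  Static structures sheared by eye motion appear as wavy
    bands; moving blood cells appear as diagonal streaks whose slope
    encodes velocity.

    ``theta`` is the angle in degrees between the vessel and the scan
    axis; the eye-motion component orthogonal to the vessel is
    ``|w1| = |v| sin(theta)`` where ``v`` is the shear measured along the
    scan axis.
    """

    data: np.ndarray
    line_rate: float = 15000.0
    space_scale: float = 1.0  # µm per pixel along the scan
    theta: float = 90.0  # degrees, vessel-to-scan-axis angle

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.size == 0:
            raise ValueError("data must be a non-empty 2-D (lines, space) array")
        if self.line_rate <= 0:
            raise ValueError("line_rate must be positive")
        if not (0.0 < self.theta <= 90.0):
            raise ValueError("theta must lie in (0, 90] degrees")

    @property
    def n_lines(self) -> int:
        return self.data.shape[0]

    @property
    def n_space(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_lines / self.line_rate


@dataclass
class ScaleModel:
    """Retinal unit conversion between microns and degrees of visual angle."""

    microns_per_degree: float = DEFAULT_MICRONS_PER_DEGREE

    def __post_init__(self) -> None:
        if self.microns_per_degree <= 0:
            raise ValueError("microns_per_degree must be positive")

    def um_to_deg(self, um: float | np.ndarray) -> float | np.ndarray:
        return um / self.microns_per_degree

    def um_to_arcmin(self, um: float | np.ndarray) -> float | np.ndarray:
        return um / self.microns_per_degree * 60.0

    def deg_to_um(self, deg: float | np.ndarray) -> float | np.ndarray:
        return deg * self.microns_per_degree


def read_video(path: str | Path, metadata: dict | None = None) -> VideoFrames:
    """Read a multi-page TIFF or AVI into a normalized :class:`VideoFrames`.

    ``metadata`` supplies ``frame_rate`` (required), ``pixel_scale`` and
    ``scale_units`` (optional), and optionally explicit ``timestamps``;
    absent timestamps are synthesized as ``k / frame_rate``.
    """
    metadata = dict(metadata or {})
    if "frame_rate" not in metadata:
        raise ValueError("metadata must supply frame_rate")
    path = Path(path)
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            import tifffile

            frames = tifffile.imread(str(path))
        else:
            import imageio.v3 as iio

            frames = iio.imread(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - backend specific
        raise IOError(f"could not read video {path}: {exc}") from exc
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim == 4:  # RGB(A) -> luminance
        frames = frames[..., :3].mean(axis=-1)
    if frames.ndim != 3:
        raise IOError(f"{path}: expected a frame stack, got shape {frames.shape}")
    return VideoFrames(
        frames=normalize_intensity(frames),
        frame_rate=float(metadata["frame_rate"]),
        timestamps=metadata.get("timestamps"),
        pixel_scale=float(metadata.get("pixel_scale", 1.0)),
        scale_units=str(metadata.get("scale_units", "px")),
    )


def write_trace(records: pd.DataFrame, path: str | Path) -> None:
    """Write a per-sample trace table as CSV (header, '.' decimal).

    NaN values (quality-gated samples) serialize as empty fields and
    round-trip back to NaN.  An empty table is an error and no file is
    created.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(records)
    if records.empty:
        raise ValueError("refusing to write an empty trace")
    records.to_csv(path, index=False, float_format="%.12g")


def read_trace(path: str | Path) -> pd.DataFrame:
    """Read back a trace CSV written by :func:`write_trace`."""
    return pd.read_csv(path)
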