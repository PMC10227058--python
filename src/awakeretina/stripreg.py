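"""Strip-based intra-frame motion correction for AOSLO videos.

A scanned frame acquired during rapid eye motion is sheared line by
line.  Splitting each frame into strips of consecutive scan lines
(default 32 lines, i.e. ~468 Hz strip sampling at a 15 kHz line rate)
and registering each strip independently to a reference frame with
zero-mean NCC undoes the shear; rigid whole-frame registration is the
baseline comparison.  Strips whose peak NCC falls below 0.5 are failed
registrations and are excluded from the rendered average.  Weak-photon
(fluorescence) inputs are pre-smoothed with a Gaussian (sigma = 5 px)
for correlation only; rendering always uses raw pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core_io import VideoFrames, get_logger
from .ncc import match_offset, ncc_map

__all__ = [
    "RegistrationConfig",
    "presmooth",
    "register_frame",
    "register_strips",
    "register_video",
    "render_registered",
    "strip_sampling_rate",
    "gradient_energy",
    "select_reference_frame",
]

log = get_logger("awakeretina.stripreg")


@dataclass
class RegistrationConfig:
    """Tunables for frame/strip registration."""

    strip_width: int = 32  # scan lines per strip
    ncc_threshold: float = 0.5  # below -> failed registration
    gaussian_sigma: float = 0.0  # pre-smoothing; 5 px for fluorescence
    reference_frame: int | None = None  # None -> automatic selection
    search_radius: int = 64  # px, both axes

    def __post_init__(self) -> None:
        if not (0.0 < self.ncc_threshold < 1.0):
            raise ValueError("ncc_threshold must lie in (0, 1)")
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")
        if self.strip_width < 1:
            raise ValueError("strip_width must be >= 1")


def strip_sampling_rate(line_rate: float, strip_width: int) -> int:
    """Effective strip sampling rate in Hz (floor): 15 kHz / 32 -> 468 Hz."""
    return int(line_rate // strip_width)


def presmooth(image: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian pre-smoothing for registration of weak-photon images.

    ``sigma = 0`` is the identity.  Applied to the correlation inputs
    only, never to rendered pixels.
    """
    if sigma <= 0:
        return np.asarray(image, dtype=np.float64)
    return ndimage.gaussian_filter(np.asarray(image, dtype=np.float64), sigma)


def register_frame(
    frame: np.ndarray,
    reference: np.ndarray,
    cfg: RegistrationConfig | None = None,
    subpixel: bool = True,
) -> tuple[float, float, float, bool]:
    """Single rigid offset of ``frame`` relative to ``reference``.

    Returns ``(dx, dy, ncc, accepted)`` where the frame content equals
    the reference content displaced by (dx, dy) (columns, rows,
    positive right/down).  ``accepted`` is False when the peak NCC falls
    below the config threshold.
    """
    cfg = cfg or RegistrationConfig()
    if frame.shape != reference.shape:
        raise ValueError("frame and reference must have the same shape")
    r = min(cfg.search_radius, (frame.shape[0] - 8) // 2,
            (frame.shape[1] - 8) // 2)
    f = presmooth(frame, cfg.gaussian_sigma)
    ref = presmooth(reference, cfg.gaussian_sigma)
    template = f[r:-r or None, r:-r or None]
    dx, dy, ncc = match_offset(ref, template, (r, r), subpixel=subpixel)
    # template cut from the moved frame is found at its un-moved position
    # in the reference, so the frame displacement is the negation
    return -dx, -dy, ncc, ncc >= cfg.ncc_threshold


def register_strips(
    frame: np.ndarray,
    reference: np.ndarray,
    cfg: RegistrationConfig | None = None,
    frame_index: int = 0,
    subpixel: bool = True,
) -> pd.DataFrame:
    """Register each strip of ``frame`` to ``reference`` independently.

    The frame is tiled into non-overlapping strips of ``strip_width``
    lines; each strip is correlated against the reference restricted to
    a window of ``search_radius`` px around its nominal position.
    Rejection (NCC < threshold) is per-strip and soft.

    Columns: frame, strip, y0, y1, dx, dy, ncc, accepted.
    """
    cfg = cfg or RegistrationConfig()
    if frame.shape != reference.shape:
        raise ValueError("frame and reference must have the same shape")
    h, w = frame.shape
    r = cfg.search_radius
    f = presmooth(frame, cfg.gaussian_sigma)
    ref = presmooth(reference, cfg.gaussian_sigma)
    rows = []
    for si, y0 in enumerate(range(0, h, cfg.strip_width)):
        y1 = min(y0 + cfg.strip_width, h)
        mx = min(r, w // 4)
        template = f[y0:y1, mx : w - mx]
        ry0 = max(y0 - r, 0)
        ry1 = min(y1 + r, h)
        rx0 = max(mx - r, 0)
        rx1 = min(w - mx + r, w)
        search = ref[ry0:ry1, rx0:rx1]
        if (search.shape[0] < template.shape[0]
                or search.shape[1] < template.shape[1]):
            rows.append(dict(frame=frame_index, strip=si, y0=y0, y1=y1,
                             dx=np.nan, dy=np.nan, ncc=np.nan, accepted=False))
            continue
        fx, fy, ncc = match_offset(search, template, (y0 - ry0, mx - rx0),
                                   subpixel=subpixel)
        dx, dy = -fx, -fy
        accepted = bool(ncc >= cfg.ncc_threshold)
        rows.append(dict(frame=frame_index, strip=si, y0=y0, y1=y1,
                         dx=dx, dy=dy, ncc=ncc, accepted=accepted))
    return pd.DataFrame(rows)


def select_reference_frame(video: VideoFrames, max_candidates: int = 8) -> int:
    """Automatic reference choice: frame maximizing mean pairwise NCC.

    Evaluated on an evenly spaced subsample of frames; a stand-in for
    the manual least-distortion choice when no index is configured.
    """
    n = video.n_frames
    idx = np.unique(np.linspace(0, n - 1, min(max_candidates, n)).astype(int))
    best, best_score = int(idx[0]), -np.inf
    for i in idx:
        score = 0.0
        for j in idx:
            if i == j:
                continue
            c = ncc_map(video.frames[j], video.frames[i][16:-16, 16:-16])
            score += float(c.max())
        if score > best_score:
            best, best_score = int(i), score
    return best


def register_video(
    video: VideoFrames, cfg: RegistrationConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Strip- and frame-register every frame of a video.

    Returns ``(strip_trace, frame_trace, reference_index)``.
    """
    cfg = cfg or RegistrationConfig()
    ref_idx = (cfg.reference_frame if cfg.reference_frame is not None
               else select_reference_frame(video))
    reference = video.frames[ref_idx]
    strip_rows = []
    frame_rows = []
    for k in range(video.n_frames):
        strip_rows.append(register_strips(video.frames[k], reference, cfg,
                                          frame_index=k))
        dx, dy, ncc, acc = register_frame(video.frames[k], reference, cfg)
        frame_rows.append(dict(frame=k, dx=dx, dy=dy, ncc=ncc, accepted=acc))
    return (pd.concat(strip_rows, ignore_index=True),
            pd.DataFrame(frame_rows), ref_idx)


def render_registered(
    video: VideoFrames,
    strip_trace: pd.DataFrame | None = None,
    frame_trace: pd.DataFrame | None = None,
    mode: str = "strip",
) -> tuple[np.ndarray, np.ndarray]:
    """Average the video after motion correction.

    ``mode`` selects the correction: ``"none"`` (plain average),
    ``"frame"`` (one rigid offset per frame), or ``"strip"`` (per-strip
    offsets; rejected strips are excluded).  Pixels never covered by an
    accepted strip are NaN (missing, not zero).

    Returns ``(average, coverage)``.
    """
    h, w = video.frame_shape
    acc = np.zeros((h, w))
    cov = np.zeros((h, w))
    if mode == "none":
        for k in range(video.n_frames):
            acc += video.frames[k]
            cov += 1.0
    elif mode == "frame":
        if frame_trace is None:
            raise ValueError("frame trace required for mode='frame'")
        for _, row in frame_trace.iterrows():
            if not row["accepted"]:
                continue
            k = int(row["frame"])
            dx = int(round(row["dx"]))
            dy = int(round(row["dy"]))
            _accumulate(acc, cov, video.frames[k], 0, h, dx, dy)
    elif mode == "strip":
        if strip_trace is None:
            raise ValueError("strip trace required for mode='strip'")
        for _, row in strip_trace.iterrows():
            if not row["accepted"]:
                continue
            k = int(row["frame"])
            y0, y1 = int(row["y0"]), int(row["y1"])
            dx = int(round(row["dx"]))
            dy = int(round(row["dy"]))
            _accumulate(acc, cov, video.frames[k], y0, y1, dx, dy)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    avg = np.full((h, w), np.nan)
    covered = cov > 0
    avg[covered] = acc[covered] / cov[covered]
    return avg, cov


def _accumulate(acc, cov, frame, y0, y1, dx, dy) -> None:
    """Place frame rows [y0, y1) at motion-corrected coordinates (-dy, -dx)."""
    h, w = frame.shape
    ty0, ty1 = y0 - dy, y1 - dy
    sx0 = max(0, dx)
    sx1 = min(w, w + dx)
    cy0 = max(ty0, 0)
    cy1 = min(ty1, h)
    if cy0 >= cy1 or sx0 >= sx1:
        return
    src_rows = slice(cy0 + dy, cy1 + dy)
    acc[cy0:cy1, sx0 - dx : sx1 - dx] += frame[src_rows, sx0:sx1]
    cov[cy0:cy1, sx0 - dx : sx1 - dx] += 1.0


def gradient_energy(image: np.ndarray) -> float:
    """Mean squared spatial gradient over finite pixels — a sharpness score."""
    img = np.asarray(image, dtype=float)
    gy, gx = np.gradient(img)
    e = gx * gx + gy * gy
    return float(np.nanmean(e))
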