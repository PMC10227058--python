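"""Blink detection and template-based retinal gaze tracking for SLO video.

Blinks darken the whole frame: a frame is flagged when its mean
intensity drops below 60 % of the whole-video mean.  Gaze is tracked by
zero-mean normalized cross-correlation of three user-selected reference
templates (optic disc, vessel junctions, ...) against every non-blink
frame; the offset of the template with the highest NCC wins and is
converted to degrees of visual angle.  Frames adjacent to a blink
(partial lid closure) and frames where every template scores below an
NCC floor are also invalidated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import VideoFrames, get_logger
from .ncc import match_offset

__all__ = [
    "Template",
    "TemplateSet",
    "detect_blinks",
    "blink_events",
    "select_templates",
    "track_gaze",
    "window_normalize",
    "gaze_velocity",
    "correlate_gaze_gait",
]

log = get_logger("awakeretina.gazetrack")

BLINK_INTENSITY_FRACTION = 0.60  # of the whole-video mean


@dataclass
class Template:
    """One reference patch: pixels plus its (row, col) origin in the reference."""

    patch: np.ndarray
    position: tuple[int, int]
    source_frame: int = 0


@dataclass
class TemplateSet:
    """Exactly three reference templates with well-defined retinal features."""

    templates: tuple[Template, Template, Template]

    def __post_init__(self) -> None:
        if len(self.templates) != 3:
            raise ValueError("a TemplateSet holds exactly 3 templates")


def detect_blinks(video: VideoFrames) -> np.ndarray:
    """Per-frame blink flags: mean frame intensity < 60 % of video mean.

    Invariant to global intensity gain (both sides scale together).
    """
    means = video.frames.mean(axis=(1, 2))
    return means < BLINK_INTENSITY_FRACTION * means.mean()


def blink_events(flags: np.ndarray, frame_rate: float) -> pd.DataFrame:
    """Group contiguous blink flags into events with start index and duration.

    Duration is ``n_frames / frame_rate`` seconds: e.g. a 3-frame event
    at 8.8 fps lasts 340.9 ms.
    """
    flags = np.asarray(flags, dtype=bool)
    rows = []
    i = 0
    while i < flags.size:
        if flags[i]:
            j = i
            while j < flags.size and flags[j]:
                j += 1
            rows.append(
                dict(start_frame=i, n_frames=j - i,
                     duration_s=(j - i) / frame_rate)
            )
            i = j
        else:
            i += 1
    return pd.DataFrame(rows, columns=["start_frame", "n_frames", "duration_s"])


def select_templates(
    reference: np.ndarray,
    positions: list[tuple[int, int]],
    size: int = 48,
    source_frame: int = 0,
) -> TemplateSet:
    """Cut three templates from a reference frame at configured positions.

    Mirrors manual template selection: positions and size come from the
    run configuration rather than a GUI.
    """
    if len(positions) != 3:
        raise ValueError("exactly 3 template positions required")
    tmpls = []
    for (r, c) in positions:
        patch = reference[r : r + size, c : c + size]
        if patch.shape != (size, size):
            raise ValueError(f"template at {(r, c)} not fully inside the frame")
        tmpls.append(Template(patch=patch.copy(), position=(r, c),
                              source_frame=source_frame))
    return TemplateSet(templates=tuple(tmpls))


def track_gaze(
    video: VideoFrames,
    templates: TemplateSet,
    ncc_floor: float = 0.3,
    subpixel: bool = True,
    invalidate_blink_neighbors: bool = True,
) -> pd.DataFrame:
    """Track per-frame retinal offset in degrees via three-template NCC.

    Each template is correlated against each non-blink frame; the
    template with the largest NCC supplies the offset, converted to
    degrees using the video's deg/px scale.  Blink frames (and their
    immediate neighbors, which suffer partial lid closure) carry no
    offset; frames where all templates fall below ``ncc_floor`` are
    invalid tracking failures.

    Columns: frame, time_s, dx_deg, dy_deg, ncc, winner, blink, valid.
    """
    if video.scale_units != "deg/px":
        log.warning("video pixel scale units are %r, expected deg/px",
                    video.scale_units)
    deg_per_px = video.pixel_scale
    blinks = detect_blinks(video)
    excluded = blinks.copy()
    if invalidate_blink_neighbors:
        excluded |= np.roll(blinks, 1) | np.roll(blinks, -1)
        if blinks.size:
            excluded[0] |= blinks[0]
            excluded[-1] |= blinks[-1]
    rows = []
    for k in range(video.n_frames):
        if excluded[k]:
            rows.append(dict(frame=k, time_s=video.timestamps[k], dx_deg=np.nan,
                             dy_deg=np.nan, ncc=np.nan, winner=-1,
                             blink=bool(blinks[k]), valid=False))
            continue
        best = None
        for ti, tmpl in enumerate(templates.templates):
            dx, dy, ncc = match_offset(video.frames[k], tmpl.patch,
                                       tmpl.position, subpixel=subpixel)
            if best is None or ncc > best[2]:
                best = (dx, dy, ncc, ti)
        dx, dy, ncc, ti = best
        ok = ncc >= ncc_floor
        rows.append(dict(frame=k, time_s=video.timestamps[k],
                         dx_deg=dx * deg_per_px if ok else np.nan,
                         dy_deg=dy * deg_per_px if ok else np.nan,
                         ncc=ncc, winner=ti if ok else -1,
                         blink=False, valid=ok))
    return pd.DataFrame(rows)


def window_normalize(trace: pd.DataFrame, window_s: float = 10.0,
                     radius_deg: float = 5.0) -> tuple[pd.DataFrame, float]:
    """Re-reference gaze to the local mean per consecutive window.

    Within each ``window_s`` window, valid offsets are centered on the
    window mean; returns the normalized trace plus the fraction of valid
    samples whose radial offset from the local mean is below
    ``radius_deg`` (the stay-within-5° statistic).  Windows with no
    valid samples contribute nothing to the fraction.
    """
    out = trace.copy()
    t = out["time_s"].to_numpy()
    if t.size and (t[-1] - t[0]) < window_s:
        raise ValueError("trace shorter than one normalization window")
    win_idx = np.floor((t - t[0]) / window_s).astype(int)
    out["dx_norm_deg"] = np.nan
    out["dy_norm_deg"] = np.nan
    within = 0
    total = 0
    for wi in np.unique(win_idx):
        sel = (win_idx == wi) & out["valid"].to_numpy()
        if not sel.any():
            continue
        mx = out.loc[sel, "dx_deg"].mean()
        my = out.loc[sel, "dy_deg"].mean()
        out.loc[sel, "dx_norm_deg"] = out.loc[sel, "dx_deg"] - mx
        out.loc[sel, "dy_norm_deg"] = out.loc[sel, "dy_deg"] - my
        r = np.hypot(out.loc[sel, "dx_norm_deg"], out.loc[sel, "dy_norm_deg"])
        within += int((r < radius_deg).sum())
        total += int(sel.sum())
    frac = within / total if total else float("nan")
    return out, frac


def gaze_velocity(trace: pd.DataFrame, frame_rate: float) -> np.ndarray:
    """Gaze speed (deg/s) per frame: centered first difference of offsets.

    Invalid frames propagate NaN.
    """
    dx = trace["dx_deg"].to_numpy()
    dy = trace["dy_deg"].to_numpy()
    vx = np.gradient(dx) * frame_rate
    vy = np.gradient(dy) * frame_rate
    return np.hypot(vx, vy)


def correlate_gaze_gait(
    gaze_speed_bins: np.ndarray, gait_speed_bins: np.ndarray
) -> dict:
    """Pearson correlation between binned |gaze velocity| and gait speed.

    Both inputs are 1 s-binned series on a common time base (NaN =
    missing bin).  A zero-variance input makes R undefined; it is
    reported as 0.0 with ``degenerate=True``.
    """
    g = np.asarray(gaze_speed_bins, dtype=float)
    w = np.asarray(gait_speed_bins, dtype=float)
    n = min(g.size, w.size)
    g, w = g[:n], w[:n]
    ok = ~np.isnan(g) & ~np.isnan(w)
    if ok.sum() < 3:
        raise ValueError("need at least 3 paired bins")
    g, w = g[ok], w[ok]
    if g.std() == 0 or w.std() == 0:
        return {"r": 0.0, "n": int(ok.sum()), "degenerate": True}
    r = float(np.corrcoef(g, w)[0, 1])
    return {"r": r, "n": int(ok.sum()), "degenerate": False}
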