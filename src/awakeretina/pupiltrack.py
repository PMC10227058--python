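"""Pupil segmentation, tracking, and beam-clipping analysis.

The exit pupil of the mouse eye appears in the pupil-camera video as a
large, nearly texture-free dark region surrounded by high-contrast fur
and eyelid.  Segmentation is texture-based: a local standard-deviation
filter highlights the surround, thresholding (STD < 0.25 on the [0, 1]
intensity scale) yields low-texture candidate regions, a watershed
splits touching regions, and the selected region's contour is fitted
with a direct least-squares ellipse.

A causal logic gate removes frames with abnormally large jumps in pupil
size or position, then beam clipping is quantified as the fraction of a
simulated circular instrument beam (2.0 or 1.6 mm diameter) falling
outside the segmented pupil, per frame and in 1 s bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.affinity import rotate as shp_rotate
from shapely.affinity import scale as shp_scale
from shapely.affinity import translate as shp_translate
from shapely.geometry import Point

from .core_io import VideoFrames, get_logger

__all__ = [
    "PupilConfig",
    "BeamSpec",
    "EllipseFit",
    "std_filter",
    "segment_pupil",
    "track_pupil",
    "gate_trace",
    "beam_clipping",
    "bin_1s",
    "circle_circle_overlap",
]

log = get_logger("awakeretina.pupiltrack")


@dataclass
class PupilConfig:
    """Tunables for pupil segmentation and trace gating.

    ``std_threshold`` is applied to the local-standard-deviation map of
    the [0, 1]-normalized frame; pixels with STD < threshold are pupil
    candidates.  The jump gates remove physiologically impossible
    frame-to-frame changes (false positives), measured causally against
    the last accepted frame.
    """

    std_window: int = 9
    std_threshold: float = 0.25
    max_center_jump: float = 50.0  # px per frame
    max_size_jump: float = 0.5  # fractional area change per frame
    min_area_frac: float = 0.01  # absolute sanity bounds on pupil area
    max_area_frac: float = 0.60

    def __post_init__(self) -> None:
        if not (0.0 < self.std_threshold < 1.0):
            raise ValueError("std_threshold must lie in (0, 1)")
        if self.std_window < 3 or self.std_window % 2 == 0:
            raise ValueError("std_window must be odd and >= 3")


@dataclass
class BeamSpec:
    """Simulated circular instrument beam at the eye's pupil plane."""

    diameter_mm: float = 2.0
    mm_per_px: float = 0.01
    center_px: tuple[float, float] | None = None  # default: mean pupil center

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("beam diameter must be positive")

    @property
    def radius_px(self) -> float:
        return self.diameter_mm / 2.0 / self.mm_per_px


@dataclass
class EllipseFit:
    """Per-frame pupil ellipse: center (x, y), semi-axes a >= b, orientation."""

    cx: float
    cy: float
    a: float
    b: float
    orientation_deg: float

    @property
    def area(self) -> float:
        return math.pi * self.a * self.b


def std_filter(frame: np.ndarray, window: int) -> np.ndarray:
    """Local standard deviation over a square window, reflected borders.

    Computed as sqrt(E[x^2] - E[x]^2) with uniform box means (population
    STD).  A constant frame maps to all zeros.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if window > min(frame.shape):
        raise ValueError("window larger than frame")
    m = ndimage.uniform_filter(frame, window, mode="reflect")
    m2 = ndimage.uniform_filter(frame * frame, window, mode="reflect")
    var = np.clip(m2 - m * m, 0.0, None)
    return np.sqrt(var)


def _fit_ellipse_to_region(mask: np.ndarray) -> EllipseFit | None:
    """Least-squares ellipse fit to the contour of a binary region."""
    from skimage import measure

    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        return None
    contour = max(contours, key=len)  # (row, col) points
    if len(contour) < 8:
        return None
    pts = contour[:, ::-1]  # -> (x, y)
    try:
        model = measure.EllipseModel.from_estimate(pts)
        if not bool(model):
            return None
        (cx, cy), (a, b), theta = model.center, model.axis_lengths, model.theta
    except AttributeError:  # scikit-image < 0.26
        model = measure.EllipseModel()
        if not model.estimate(pts):
            return None
        cx, cy, a, b, theta = model.params
    if a < b:
        a, b = b, a
        theta += math.pi / 2
    if a <= 0 or b <= 0 or not np.isfinite([cx, cy, a, b, theta]).all():
        return None
    return EllipseFit(cx=float(cx), cy=float(cy), a=float(a), b=float(b),
                      orientation_deg=float(np.rad2deg(theta) % 180.0))


def segment_pupil(
    frame: np.ndarray,
    cfg: PupilConfig | None = None,
    prev_center: tuple[float, float] | None = None,
) -> EllipseFit | None:
    """Segment the pupil in one frame; None when no acceptable region exists.

    Pipeline: STD filter -> threshold (STD < ``cfg.std_threshold``) ->
    watershed split of touching low-texture regions (seeded at regional
    minima of the texture map) -> pick the region nearest the previous
    detection (largest if none) -> contour ellipse fit.  Regions outside
    the absolute area bounds are rejected.
    """
    from skimage.segmentation import watershed

    cfg = cfg or PupilConfig()
    texture = std_filter(frame, cfg.std_window)
    candidate = texture < cfg.std_threshold
    if not candidate.any():
        return None
    # seeds: connected regional minima of the (smoothed) texture map
    smoothed = ndimage.gaussian_filter(texture, 2.0)
    minima = smoothed < np.percentile(smoothed[candidate], 25)
    markers, n_mark = ndimage.label(minima & candidate)
    if n_mark == 0:
        markers, n_mark = ndimage.label(candidate)
    labels = watershed(smoothed, markers=markers, mask=candidate)

    n_px = frame.size
    best = None
    best_key = -np.inf
    for lab in range(1, labels.max() + 1):
        region = labels == lab
        area = int(region.sum())
        if not (cfg.min_area_frac * n_px <= area <= cfg.max_area_frac * n_px):
            continue
        if prev_center is not None:
            cy, cx = ndimage.center_of_mass(region)
            key = -math.hypot(cx - prev_center[0], cy - prev_center[1])
        else:
            key = float(area)
        if key > best_key:
            best_key = key
            best = region
    if best is None:
        return None
    best = ndimage.binary_fill_holes(best)
    fit = _fit_ellipse_to_region(best)
    if fit is None:
        return None
    # reject fits that are not plausibly the pupil (degenerate/huge)
    if fit.area > cfg.max_area_frac * n_px or fit.area < cfg.min_area_frac * n_px:
        return None
    return fit


def track_pupil(video: VideoFrames, cfg: PupilConfig | None = None) -> pd.DataFrame:
    """Segment every frame and return the raw (ungated) ellipse trace.

    Columns: frame, time_s, cx, cy, a, b, orientation_deg, area, valid.
    Invalid frames carry NaN geometry.
    """
    cfg = cfg or PupilConfig()
    rows = []
    prev_center = None
    for k in range(video.n_frames):
        fit = segment_pupil(video.frames[k], cfg, prev_center=prev_center)
        if fit is not None:
            prev_center = (fit.cx, fit.cy)
            rows.append(
                dict(frame=k, time_s=video.timestamps[k], cx=fit.cx, cy=fit.cy,
                     a=fit.a, b=fit.b, orientation_deg=fit.orientation_deg,
                     area=fit.area, valid=True)
            )
        else:
            rows.append(
                dict(frame=k, time_s=video.timestamps[k], cx=np.nan, cy=np.nan,
                     a=np.nan, b=np.nan, orientation_deg=np.nan, area=np.nan,
                     valid=False)
            )
    return pd.DataFrame(rows)


def gate_trace(
    raw: pd.DataFrame, cfg: PupilConfig | None = None,
    frame_shape: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Causal logic gate removing abnormally large, rapid pupil changes.

    A frame is invalidated when its center moves more than
    ``max_center_jump`` px or its area changes by more than
    ``max_size_jump`` (fractional) relative to the *last accepted*
    frame.  The gate is seeded by the first frame passing the absolute
    area sanity bounds (when ``frame_shape`` is given) or simply the
    first valid frame.
    """
    cfg = cfg or PupilConfig()
    if len(raw) < 2:
        return raw.copy()
    out = raw.copy()
    valid = out["valid"].to_numpy().copy()
    cx = out["cx"].to_numpy()
    cy = out["cy"].to_numpy()
    area = out["area"].to_numpy()
    n_px = frame_shape[0] * frame_shape[1] if frame_shape else None

    def sane(i: int) -> bool:
        if not valid[i]:
            return False
        if n_px is None:
            return True
        return cfg.min_area_frac * n_px <= area[i] <= cfg.max_area_frac * n_px

    last = None
    for i in range(len(out)):
        if not valid[i]:
            continue
        if last is None:
            if sane(i):
                last = i
            else:
                valid[i] = False
            continue
        jump = math.hypot(cx[i] - cx[last], cy[i] - cy[last])
        rel_area = abs(area[i] - area[last]) / area[last]
        if jump > cfg.max_center_jump or rel_area > cfg.max_size_jump:
            valid[i] = False
        else:
            last = i
    out["valid"] = valid
    for col in ("cx", "cy", "a", "b", "orientation_deg", "area"):
        out.loc[~out["valid"], col] = np.nan
    return out


# ---------------------------------------------------------------------------
# beam clipping
# ---------------------------------------------------------------------------

#: polygonization resolution of the beam circle / pupil ellipse
#: (quad_segs=512 -> 2048-gon; agrees with the circle-circle closed
#: form to better than 0.1 %)
_QUAD_SEGS = 512


def _ellipse_polygon(fit: EllipseFit):
    e = Point(0.0, 0.0).buffer(1.0, quad_segs=_QUAD_SEGS)
    e = shp_scale(e, fit.a, fit.b)
    e = shp_rotate(e, fit.orientation_deg, origin=(0, 0))
    return shp_translate(e, fit.cx, fit.cy)


def circle_circle_overlap(d: float, r1: float, r2: float) -> float:
    """Closed-form lens area of two circles with center distance ``d``.

    Used as the analytic oracle for the polygonal intersection.
    """
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return math.pi * r * r
    d1 = (d * d + r1 * r1 - r2 * r2) / (2 * d)
    d2 = d - d1
    a1 = r1 * r1 * math.acos(np.clip(d1 / r1, -1, 1)) - d1 * math.sqrt(
        max(r1 * r1 - d1 * d1, 0.0)
    )
    a2 = r2 * r2 * math.acos(np.clip(d2 / r2, -1, 1)) - d2 * math.sqrt(
        max(r2 * r2 - d2 * d2, 0.0)
    )
    return a1 + a2


def beam_clipping(
    trace: pd.DataFrame,
    beam: BeamSpec,
    unclipped_threshold: float = 0.10,
) -> dict:
    """Quantify clipping of a static circular beam by the tracked pupil.

    Per valid frame the clipped fraction is ``1 - area(beam ∩ pupil) /
    area(beam)``, computed by polygonal intersection of the beam circle
    with the fitted pupil ellipse.  The beam sits at the mean valid
    pupil center unless ``beam.center_px`` pins it.

    Returns a report dict with the per-frame series, mean clipped
    percentage, and the fraction of frames clipped by less than
    ``unclipped_threshold`` (frames at exactly the threshold count as
    clipped).
    """
    valid = trace[trace["valid"].astype(bool)]
    if valid.empty:
        raise ValueError("no valid frames to evaluate beam clipping")
    if beam.center_px is not None:
        bx, by = beam.center_px
    else:
        bx, by = float(valid["cx"].mean()), float(valid["cy"].mean())
    beam_poly = Point(bx, by).buffer(beam.radius_px, quad_segs=_QUAD_SEGS)
    beam_area = beam_poly.area

    clipped = np.full(len(trace), np.nan)
    for i, row in trace.iterrows():
        if not row["valid"]:
            continue
        fit = EllipseFit(row["cx"], row["cy"], row["a"], row["b"],
                         row["orientation_deg"])
        inter = beam_poly.intersection(_ellipse_polygon(fit)).area
        clipped[trace.index.get_loc(i)] = 1.0 - inter / beam_area
    ok = ~np.isnan(clipped)
    frac_unclipped = float(np.mean(clipped[ok] < unclipped_threshold))
    return {
        "beam_center_px": (bx, by),
        "beam_diameter_mm": beam.diameter_mm,
        "clipped_fraction": clipped,
        "time_s": trace["time_s"].to_numpy(),
        "mean_clipped_pct": float(np.nanmean(clipped) * 100.0),
        "frac_frames_unclipped": frac_unclipped,
        "n_valid_frames": int(ok.sum()),
    }


def bin_1s(values: np.ndarray, timestamps: np.ndarray) -> np.ndarray:
    """Average a per-frame series into 1 s bins (floor boundaries).

    Bins with no samples are NaN (missing, not zero) — acquisition gaps
    stay visible.  Bin count = ceil(duration) with duration measured
    from t=0 to the last timestamp inclusive.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    values = np.asarray(values, dtype=float)
    if timestamps.size == 0:
        return np.empty(0)
    n_bins = int(np.floor(timestamps.max())) + 1
    idx = np.floor(timestamps).astype(int)
    out = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = (idx == b) & ~np.isnan(values)
        if sel.any():
            out[b] = values[sel].mean()
    return out
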