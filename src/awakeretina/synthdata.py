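"""Synthetic ground-truth data generators for every pipeline stage.

Each generator emulates one class of raw recording from the awake-mouse
imaging rig and returns both the data and the ground truth used to
produce it, in the same units the analysis stages report, so recovery
tests are direct subtractions:

* :func:`gen_pupil_video` — pupil-camera video: a low-texture elliptical
  pupil drifting on a high-texture speckle background, with blinks
  rendered as global darkening.
* :func:`gen_slo_video` — retinal SLO video: one retina-like texture
  translated by a gaze trace, with dark blink frames.
* :func:`gen_linescan` — 15 kHz line-scan space-time image: a vessel
  band sheared by a band-limited micro-tremor trace plus respiratory
  (2 Hz) and cardiac (9 Hz) components, with diagonal blood-cell
  streaks of known velocity.
* :func:`gen_oct_volume` — OCT B-scan stack with smooth ILM and OS-RPE
  boundaries separated by a known thickness map.
* :func:`gen_quadrature` — two-channel quadrature encoder pulse trains
  for a known wheel-speed profile.

All generators are pure functions of ``(parameters, seed)``; RNG
streams are derived per-generator from the master seed so regeneration
is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_io import SpaceTimeImage, VideoFrames

__all__ = [
    "TremorModel",
    "PupilScene",
    "StreakModel",
    "gen_pupil_video",
    "gen_slo_video",
    "gen_linescan",
    "gen_oct_volume",
    "gen_quadrature",
    "retina_texture",
    "tremor_trace",
]

# Stream ids keep per-generator RNG sequences independent of each other
# while all deriving from one master seed.
_STREAMS = {
    "pupil": 11,
    "slo": 22,
    "linescan": 33,
    "oct": 44,
    "quadrature": 55,
    "texture": 66,
    "tremor": 77,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


# ---------------------------------------------------------------------------
# parameter models
# ---------------------------------------------------------------------------


@dataclass
class TremorModel:
    """Generative model of awake-mouse fixational eye motion.

    The micro-tremor is synthesized as white noise band-limited to
    ``[band_lo, band_hi]`` Hz and scaled to ``rms_amplitude``; slower
    respiratory and cardiac components are added as sinusoids at
    ``resp_freq`` (2 Hz) and ``cardiac_freq`` (9 Hz).  Amplitudes are in
    microns of retinal motion orthogonal to the scanned vessel.
    """

    band_lo: float = 30.0
    band_hi: float = 200.0
    rms_amplitude: float = 2.0
    resp_freq: float = 2.0
    cardiac_freq: float = 9.0
    resp_amp: float = 3.0
    cardiac_amp: float = 1.5
    seed: int = 0

    def validate(self, line_rate: float) -> None:
        if not (0 < self.band_lo < self.band_hi < line_rate / 2):
            raise ValueError("need 0 < band_lo < band_hi < line_rate/2")
        for a in (self.rms_amplitude, self.resp_amp, self.cardiac_amp):
            if a < 0:
                raise ValueError("amplitudes must be non-negative")


@dataclass
class PupilScene:
    """Scene description for the synthetic pupil-camera video."""

    shape: tuple[int, int] = (192, 192)
    center: tuple[float, float] = (96.0, 96.0)  # (x, y) px at frame 0
    drift_px_per_frame: tuple[float, float] = (0.0, 0.0)
    semi_axes: tuple[float, float] = (40.0, 32.0)  # (a, b) px
    orientation_deg: float = 0.0
    background_contrast: float = 0.8
    blink_intervals: tuple[tuple[float, float], ...] = ()
    mm_per_px: float = 0.01
    seed: int = 0

    def center_at(self, k: int) -> tuple[float, float]:
        return (
            self.center[0] + k * self.drift_px_per_frame[0],
            self.center[1] + k * self.drift_px_per_frame[1],
        )


@dataclass
class StreakModel:
    """Blood-cell streaks drawn inside the vessel band of a line scan.

    ``velocities`` are cell speeds in mm/s (within the 0.03-1275 mm/s
    measurement bandwidth); ``streaks_per_ms`` sets the cell arrival
    density.  Streak slope in the space-time image is
    ``v / (space_scale * line_rate)`` px per line.
    """

    velocities: tuple[float, ...] = (10.0,)
    streaks_per_ms: float = 2.0
    band_center_px: float = 64.0
    band_halfwidth_px: float = 20.0
    contrast: float = 0.5
    streak_sigma_px: float = 2.0  # cell cross-section (~4-5 µm at 1 µm/px)
    seed: int = 0

    def validate(self) -> None:
        for v in self.velocities:
            if not (0.03 < abs(v) < 1275.0):
                raise ValueError(
                    f"cell velocity {v} mm/s outside the 0.03-1275 mm/s bandwidth"
                )


# ---------------------------------------------------------------------------
# shared texture / trace helpers
# ---------------------------------------------------------------------------


def retina_texture(
    shape: tuple[int, int],
    seed: int = 0,
    smooth_px: float = 3.0,
    vessel_contrast: float = 0.5,
    n_vessels: int = 4,
) -> np.ndarray:
    """Retina-like texture: smoothed random field plus dark curvilinear vessels.

    Gives NCC trackers realistic mid-frequency features (nerve-fiber
    mottle) and strong dark edges (vessels) without modelling optics.
    """
    rng = _rng(seed, "texture")
    h, w = shape
    base = ndimage.gaussian_filter(rng.standard_normal((h, w)), smooth_px)
    base = (base - base.min()) / (base.max() - base.min() + 1e-12)
    # dark wavy vessels of varying width crossing the field
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_vessels):
        x0 = rng.uniform(0.1 * w, 0.9 * w)
        angle = rng.uniform(0, np.pi)
        amp = rng.uniform(0.02, 0.08) * w
        freq = rng.uniform(1.0, 3.0)
        width = rng.uniform(1.5, 4.0)
        u = xx * np.cos(angle) + yy * np.sin(angle)
        v = -xx * np.sin(angle) + yy * np.cos(angle)
        path = x0 + amp * np.sin(2 * np.pi * freq * v / max(h, w))
        dist = np.abs(u - path)
        base *= 1.0 - vessel_contrast * np.exp(-0.5 * (dist / width) ** 2)
    base = 0.15 + 0.7 * base
    return np.clip(base, 0.0, 1.0)


def tremor_trace(
    model: TremorModel, n_samples: int, sample_rate: float
) -> np.ndarray:
    """Eye-motion trace in µm: band-limited noise + 2 Hz and 9 Hz sinusoids.

    The band-limited part is white Gaussian noise whose FFT is masked to
    ``[band_lo, band_hi]`` and rescaled to the requested RMS.
    """
    model.validate(sample_rate)
    rng = _rng(model.seed, "tremor")
    t = np.arange(n_samples) / sample_rate
    trace = np.zeros(n_samples)
    if model.rms_amplitude > 0:
        white = rng.standard_normal(n_samples)
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n_samples, 1.0 / sample_rate)
        mask = (freqs >= model.band_lo) & (freqs <= model.band_hi)
        spec[~mask] = 0.0
        band = np.fft.irfft(spec, n_samples)
        rms = np.sqrt(np.mean(band**2))
        if rms > 0:
            trace += band * (model.rms_amplitude / rms)
    if model.resp_amp > 0:
        trace += model.resp_amp * np.sin(2 * np.pi * model.resp_freq * t)
    if model.cardiac_amp > 0:
        trace += model.cardiac_amp * np.sin(2 * np.pi * model.cardiac_freq * t)
    return trace


def _in_blink(t: float, intervals) -> bool:
    return any(lo <= t < hi for lo, hi in intervals)


# ---------------------------------------------------------------------------
# pupil video
# ---------------------------------------------------------------------------


def gen_pupil_video(
    scene: PupilScene, n_frames: int, frame_rate: float = 8.8
) -> tuple[VideoFrames, dict]:
    """Render a pupil-camera video plus its ground-truth ellipse trace.

    The pupil interior is a near-uniform dark ellipse (low spatial
    variance); the surround is high-contrast speckle (fur/eyelid
    analogue), so a local-standard-deviation filter separates the two.
    Blink intervals darken whole frames below 60 % of the video mean.

    Returns ``(video, truth)`` where ``truth`` maps frame index to
    center/semi-axes/orientation and carries the blink intervals.
    """
    h, w = scene.shape
    a, b = scene.semi_axes
    for k in range(n_frames):
        cx, cy = scene.center_at(k)
        if not (a < cx < w - a and b < cy < h - b):
            raise ValueError(f"pupil leaves the frame at frame {k}")
    if 2 * a >= w or 2 * b >= h:
        raise ValueError("pupil larger than frame")

    rng = _rng(scene.seed, "pupil")
    # static speckle background, high local variance
    speckle = rng.uniform(0.5 - scene.background_contrast / 2,
                          0.5 + scene.background_contrast / 2, (h, w))
    speckle = 0.5 + (speckle - 0.5) * 1.0
    yy, xx = np.mgrid[0:h, 0:w]
    phi = np.deg2rad(scene.orientation_deg)
    frames = np.empty((n_frames, h, w))
    centers = np.empty((n_frames, 2))
    timestamps = np.arange(n_frames) / frame_rate
    for k in range(n_frames):
        cx, cy = scene.center_at(k)
        centers[k] = (cx, cy)
        xr = (xx - cx) * np.cos(phi) + (yy - cy) * np.sin(phi)
        yr = -(xx - cx) * np.sin(phi) + (yy - cy) * np.cos(phi)
        inside = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
        frame = speckle.copy()
        # pupil: dark, nearly uniform (tiny sensor noise only)
        frame[inside] = 0.08 + 0.01 * rng.standard_normal(int(inside.sum()))
        frame = np.clip(frame, 0.0, 1.0)
        if _in_blink(timestamps[k], scene.blink_intervals):
            frame = frame * 0.3  # global darkening well below the 60 % rule
        frames[k] = frame
    video = VideoFrames(
        frames=np.clip(frames, 0, 1),
        frame_rate=frame_rate,
        pixel_scale=scene.mm_per_px,
        scale_units="mm/px",
    )
    truth = {
        "center_px": centers,
        "semi_axes_px": (a, b),
        "orientation_deg": scene.orientation_deg,
        "blink_intervals": scene.blink_intervals,
        "mm_per_px": scene.mm_per_px,
    }
    return video, truth


# ---------------------------------------------------------------------------
# SLO retinal video
# ---------------------------------------------------------------------------


def gen_slo_video(
    motion_deg: np.ndarray,
    deg_per_px: float,
    blink_frames: tuple[int, ...] = (),
    base: np.ndarray | None = None,
    frame_rate: float = 8.8,
    shape: tuple[int, int] = (256, 256),
    noise: float = 0.01,
    seed: int = 0,
) -> tuple[VideoFrames, dict]:
    """Render an SLO retinal video as one texture translated by a gaze trace.

    ``motion_deg`` is ``(n_frames, 2)`` of (dx, dy) gaze offsets in
    degrees; each frame is the base texture shifted by the offset
    (sub-pixel, cubic interpolation) plus Gaussian noise.  Frames listed
    in ``blink_frames`` are scaled to 40 % of the mean intensity, below
    the 60 %-of-mean blink threshold.
    """
    motion_deg = np.atleast_2d(np.asarray(motion_deg, dtype=float))
    n_frames = motion_deg.shape[0]
    if base is None:
        base = retina_texture(shape, seed=seed)
    h, w = base.shape
    motion_px = motion_deg / deg_per_px
    max_shift = np.abs(motion_px).max() if motion_px.size else 0.0
    if max_shift > 0.5 * min(h, w):
        raise ValueError("gaze motion too large: frame overlap below 25% of area")
    rng = _rng(seed, "slo")
    frames = np.empty((n_frames, h, w))
    for k in range(n_frames):
        dx, dy = motion_px[k]
        # content moves by (+dx, +dy): sample the base at shifted coordinates
        frame = ndimage.shift(base, (dy, dx), order=3, mode="reflect")
        frame = frame + noise * rng.standard_normal((h, w))
        frames[k] = frame
    frames = np.clip(frames, 0.0, 1.0)
    mean_level = frames.mean()
    for k in blink_frames:
        frames[k] = frames[k] * (0.4 * mean_level / max(frames[k].mean(), 1e-9))
    video = VideoFrames(
        frames=np.clip(frames, 0, 1),
        frame_rate=frame_rate,
        pixel_scale=deg_per_px,
        scale_units="deg/px",
    )
    truth = {
        "offsets_deg": motion_deg,
        "offsets_px": motion_px,
        "blink_frames": tuple(blink_frames),
        "deg_per_px": deg_per_px,
        "base": base,
    }
    return video, truth


# ---------------------------------------------------------------------------
# line-scan space-time image
# ---------------------------------------------------------------------------


def _vessel_profile(x: np.ndarray, center: float, halfwidth: float) -> np.ndarray:
    """Dark vessel band with soft (1-px) edges on a bright background."""
    edge = 1.0
    d = np.abs(x - center)
    return 1.0 - 0.6 / (1.0 + np.exp((d - halfwidth) / edge))


def gen_linescan(
    tremor: TremorModel | None,
    streaks: StreakModel | None,
    n_lines: int = 4096,
    n_space: int = 128,
    line_rate: float = 15000.0,
    space_scale: float = 1.0,
    theta: float = 90.0,
    noise: float = 0.02,
    seed: int = 0,
) -> tuple[SpaceTimeImage, dict]:
    """Render a line-scan space-time image with known motion and streaks.

    The vessel band is displaced line-by-line along the scan axis by
    ``w1(t) / sin(theta)`` where ``w1`` is the ground-truth orthogonal
    motion trace in µm — i.e. the sin(theta) projection is applied at
    generation so the analysis recovers ``w1`` directly.  Blood-cell
    streaks are drawn inside the band at slope ``v/(space_scale *
    line_rate)`` px per line with anti-aliased Gaussian cross-sections.

    Returns ``(SpaceTimeImage, truth)`` with truth keys ``w1_um``
    (per-line orthogonal motion), ``shear_px`` (per-line along-scan
    displacement in px) and ``velocities_mm_s``.
    """
    if n_lines < 2048:
        raise ValueError("need at least 2048 lines for spectral analysis")
    sin_t = np.sin(np.deg2rad(theta))
    if tremor is not None:
        w1_um = tremor_trace(tremor, n_lines, line_rate)
    else:
        w1_um = np.zeros(n_lines)
    shear_um = w1_um / sin_t
    shear_px = shear_um / space_scale

    band = streaks if streaks is not None else StreakModel(velocities=())
    if band.velocities:
        band.validate()
    center0 = band.band_center_px
    halfw = band.band_halfwidth_px
    max_off = np.abs(shear_px).max() if n_lines else 0.0
    if center0 - halfw - max_off < 1 or center0 + halfw + max_off > n_space - 1:
        raise ValueError("vessel band leaves the scan field under the given motion")

    x = np.arange(n_space, dtype=float)
    img = np.empty((n_lines, n_space))
    centers = center0 + shear_px
    for i in range(n_lines):
        img[i] = _vessel_profile(x, centers[i], halfw)

    # blood-cell streaks: each cell crosses the band once, moving at
    # v px/line; rendered as a dark Gaussian dot per line (anti-aliased)
    rng = _rng(seed, "linescan")
    if band.velocities:
        duration_ms = n_lines / line_rate * 1000.0
        n_cells = max(1, int(round(band.streaks_per_ms * duration_ms)))
        vels = rng.choice(np.asarray(band.velocities, dtype=float), size=n_cells)
        births = rng.uniform(0, n_lines, size=n_cells)
        sigma = band.streak_sigma_px
        for v_mm, t0 in zip(vels, births):
            slope = max(abs(v_mm) * 1000.0 / (space_scale * line_rate), 1e-9)
            # each cell crosses the lumen once: a straight segment from
            # the lower to the upper band edge in the band-relative frame
            # (the eye-motion shear is added back per line), rendered as
            # a Gaussian capsule of true perpendicular width `sigma`
            t1 = t0 + 2 * halfw / slope
            pad = int(np.ceil(4 * sigma))
            r0 = max(int(np.floor(t0)) - pad, 0)
            r1 = min(int(np.ceil(t1)) + pad + 1, n_lines)
            if r0 >= r1:
                continue
            rows = np.arange(r0, r1, dtype=float)[:, None]
            xrel = x[None, :] - centers[r0:r1][:, None]  # band-relative x
            # segment P0=(t0, -halfw) -> P1=(t1, +halfw) in (line, xrel)
            ut, ux = t1 - t0, 2.0 * halfw
            norm2 = ut * ut + ux * ux
            wt = rows - t0
            wx = xrel + halfw
            c = np.clip((wt * ut + wx * ux) / norm2, 0.0, 1.0)
            d2 = (wt - c * ut) ** 2 + (wx - c * ux) ** 2
            img[r0:r1] -= band.contrast * np.exp(-0.5 * d2 / sigma**2)

    img += noise * rng.standard_normal(img.shape)
    img = np.clip(img, 0.0, 1.0)
    st = SpaceTimeImage(
        data=img, line_rate=line_rate, space_scale=space_scale, theta=theta
    )
    truth = {
        "w1_um": w1_um,
        "shear_px": shear_px,
        "velocities_mm_s": tuple(band.velocities),
        "band_center_px": center0,
        "band_halfwidth_px": halfw,
    }
    return st, truth


# ---------------------------------------------------------------------------
# OCT volume
# ---------------------------------------------------------------------------


def gen_oct_volume(
    thickness_map_um: np.ndarray,
    axial_scale: float = 2.0,
    depth_px: int = 256,
    noise: float = 0.05,
    ilm_base_px: float = 60.0,
    curvature_px: float = 10.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Render an OCT B-scan stack with known ILM and OS-RPE boundaries.

    ``thickness_map_um`` is the en-face total-retinal-thickness grid,
    shape ``(n_bscans, width)``.  Per B-scan the ILM follows a smooth
    curve (gentle sinusoidal sag of amplitude ``curvature_px``); the
    OS-RPE boundary sits ``thickness/axial_scale`` pixels deeper.  The
    vitreous above the ILM is dark, the retina moderately bright with a
    brighter RPE band, and below the RPE dark again; multiplicative
    speckle noise is added.

    Returns ``(volume, truth)`` with volume shape
    ``(n_bscans, depth_px, width)`` and truth rows (float px) for both
    boundaries.
    """
    tmap = np.asarray(thickness_map_um, dtype=float)
    n_scans, width = tmap.shape
    thick_px = tmap / axial_scale
    if np.any(ilm_base_px + curvature_px + thick_px + 10 >= depth_px):
        raise ValueError("thickness exceeds the axial extent of the volume")

    cols = np.arange(width)
    scans = np.arange(n_scans)
    sag = (
        curvature_px
        * np.outer(
            np.sin(np.pi * (scans + 0.5) / n_scans),
            np.sin(np.pi * (cols + 0.5) / width),
        )
    )
    ilm_rows = ilm_base_px + sag
    rpe_rows = ilm_rows + thick_px

    rng = _rng(seed, "oct")
    depth = np.arange(depth_px, dtype=float)[None, :, None]  # (1, depth, 1)
    ilm = ilm_rows[:, None, :]
    rpe = rpe_rows[:, None, :]
    # smooth intensity model: dark vitreous -> retina 0.55 -> RPE band 0.9 -> dark
    edge = 1.0
    inside = 1.0 / (1.0 + np.exp(-(depth - ilm) / edge)) * (
        1.0 / (1.0 + np.exp((depth - rpe) / edge))
    )
    rpe_band = np.exp(-0.5 * ((depth - (rpe - 3.0)) / 3.0) ** 2)
    vol = 0.08 + 0.45 * inside + 0.4 * rpe_band * inside
    if noise > 0:
        vol = vol * (1.0 + noise * rng.standard_normal(vol.shape))
    vol = np.clip(vol, 0.0, 1.0)
    truth = {
        "ilm_rows": ilm_rows,
        "rpe_rows": rpe_rows,
        "trt_um": tmap.copy(),
        "axial_scale": axial_scale,
    }
    return vol, truth


# ---------------------------------------------------------------------------
# quadrature encoder
# ---------------------------------------------------------------------------

# quadrature state sequence for forward rotation: (A,B) gray code
_QUAD_STATES = np.array([0b00, 0b01, 0b11, 0b10])


def gen_quadrature(
    speed_profile: np.ndarray,
    sample_rate: float,
    cpr: int = 256,
    wheel_diameter: float = 0.090,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Synthesize A/B encoder pulse trains for a wheel-speed profile.

    ``speed_profile`` is the wheel surface speed in m/s sampled at
    ``sample_rate``.  The wheel position is integrated, converted to
    quarter-count phase (4 transitions per encoder count), and emitted
    as quadrature square waves.  Raises if the maximum edge rate exceeds
    ``sample_rate / 20`` (aliasing guard).

    Returns ``(chA, chB, truth)`` with truth carrying the speed profile,
    total distance, and the per-1-s-bin mean speeds.
    """
    speed = np.asarray(speed_profile, dtype=float)
    if np.any(speed < 0):
        raise ValueError("speeds must be non-negative")
    circumference = np.pi * wheel_diameter
    max_edge_rate = 4.0 * cpr * speed.max() / circumference
    if max_edge_rate > sample_rate / 20.0:
        raise ValueError(
            f"edge rate {max_edge_rate:.0f}/s would alias at {sample_rate} Hz; "
            "increase sample_rate"
        )
    distance = np.cumsum(speed) / sample_rate  # m, trapezoid not needed here
    phase = np.floor(distance / circumference * cpr * 4.0).astype(np.int64)
    states = _QUAD_STATES[phase % 4]
    chA = ((states >> 1) & 1).astype(np.int8)
    chB = (states & 1).astype(np.int8)
    t = np.arange(speed.size) / sample_rate
    n_bins = int(np.ceil(t[-1])) if speed.size > 1 else 1
    bin_idx = np.minimum(np.floor(t).astype(int), max(n_bins - 1, 0))
    bin_speed = np.array(
        [speed[bin_idx == b].mean() if np.any(bin_idx == b) else np.nan
         for b in range(max(n_bins, 1))]
    )
    truth = {
        "speed": speed,
        "total_distance_m": float(distance[-1]) if speed.size else 0.0,
        "bin_speed_m_s": bin_speed,
        "cpr": cpr,
        "wheel_diameter_m": wheel_diameter,
        "sample_rate": sample_rate,
    }
    return chA, chB, truth
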