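# Methods

This note documents the models, algorithms, parameter choices, and
known limitations of the `awake-retina` pipeline. The package analyzes
recordings from head-fixed, awake-behaving mouse retinal imaging rigs —
pupil-camera video, SLO/AOSLO frame stacks, 15 kHz line-scan space-time
images, OCT volumes, and wheel-encoder traces — and ships a synthetic
generator for each input so every stage is testable against known
ground truth without any recorded data.

## Conventions

Pixels are 0-based, row-major, origin top-left. Displacements are
`(dx, dy)` = (columns, rows), positive right/down. Intensities are
min-max normalized to [0, 1] **per video** (not per frame) at load
time, so rules phrased as fractions of the video mean — in particular
the blink rule — are well defined. Timestamps are float seconds;
acquisition gaps are timestamp jumps, never filler frames. Retinal
distances convert between microns and visual angle at 34 µm/deg
(configurable), the value implied by quoting the same motion amplitude
as 5.95 µm and 10.50 arcmin.

## Pupil tracking and beam clipping

The exit pupil appears as a large near-uniform dark region surrounded
by high-contrast fur and lid. Segmentation is texture-based: a local
standard-deviation filter (window 9 px, population STD, reflected
borders), a threshold of STD < 0.25 on the normalized intensity scale,
a watershed seeded at regional minima of the smoothed texture map to
split touching low-texture regions, and a direct least-squares ellipse
fit to the winning region's contour. Region selection prefers the
region nearest the previous detection (largest when none), with
absolute area sanity bounds of 1–60 % of the frame.

A causal logic gate invalidates frames whose center jumps more than
50 px or whose area changes more than 50 % relative to the last
*accepted* frame; the gate seeds on the first frame passing the
absolute bounds. These two defaults quantify "abnormally large and
rapid" changes; they are configurable.

Beam clipping per frame is `1 − area(beam ∩ pupil)/area(beam)` for a
static circular beam (2.0 or 1.6 mm diameter) centered by default at
the mean valid pupil center. The intersection uses 2048-gon polygons
(shapely); it agrees with the circle–circle lens closed form to better
than 0.1 %, which the tests verify as an oracle. A frame counts as
"unclipped" when its clipped fraction is strictly below 0.10 (ties
clip). The per-frame series is averaged into 1 s bins with floor
boundaries; empty bins are missing (NaN), never zero.

## Blink detection and gaze tracking

A frame is a blink when its mean intensity falls below 60 % of the
whole-video mean — a rule invariant to global gain. Contiguous flagged
frames group into events; duration is `n/frame_rate` (three frames at
8.8 fps = 340.9 ms). Gaze is tracked with three reference templates
(positions and size from configuration, standing in for interactive
selection) matched by zero-mean normalized cross-correlation; the
template with the highest NCC supplies the frame offset, refined to
sub-pixel precision by a 3-point parabolic fit and converted to degrees.
Blink frames and their immediate neighbors (partial lid closure) carry
no offset; frames where every template scores below NCC 0.3 are
tracking failures. Gaze stability is summarized by re-referencing
offsets to the local mean in consecutive 10 s windows and reporting
the fraction of valid samples within 5° of that mean. Gaze velocity is
the centered first difference times the frame rate; correlation with
locomotion uses Pearson's R over paired 1 s bins, with zero-variance
inputs reported as R = 0 and flagged degenerate.

## Strip registration

Intra-frame motion shears scanned frames line by line. Each frame is
tiled into non-overlapping strips of 32 scan lines (≈468 Hz strip
sampling at 15 kHz, just above Nyquist for the ~200 Hz upper edge of
the tremor band) and each strip is registered to a reference frame by
zero-mean NCC within a ±64 px search window around its nominal
position. Strips with peak NCC below 0.5 are failed registrations and
are excluded from rendering. Rigid whole-frame registration (one offset
per frame) is the baseline. Weak-photon fluorescence channels are
pre-smoothed with a σ = 5 px Gaussian for correlation only; rendering
always accumulates raw pixels at motion-corrected integer coordinates,
with the average normalized by per-pixel coverage and uncovered pixels
left missing. The reference frame is user-selected by index;
the automatic fallback maximizes mean pairwise NCC over a frame
subsample. Sharpness comparisons use mean squared gradient energy, and
on sheared synthetic video the ordering none < frame < strip holds.

## Line-scan micro-tremor extraction

A 1-D beam scanned across a major vessel at 15 kHz yields a space-time
image in which eye motion shears the vessel band along the scan axis.
The shear trace is extracted by strip-wise 1-D correlation: twenty
32-line reference strips are chosen at random (seeded), each line-strip
profile is matched against each reference with per-window-normalized
1-D NCC, candidates are zero-centered, points whose integer-precision
change from the previous point exceeds 10 px are discarded as false
positives, and the surviving candidates merge by point-wise median
(invalid where fewer than half survive; global failure above 50 %
invalid). Sub-pixel shifts use log-domain parabolic interpolation of
the correlation peak — exact for Gaussian-shaped peaks and much less
prone to pixel locking than a plain parabola (a plain parabola
under-recovered sinusoid amplitudes by ~9 % in validation). Strip-level
estimates sit at strip centers and are interpolated to per-line
resolution with a cubic spline; linear interpolation of a ~100 Hz
signal sampled at ~468 Hz loses ~14 % amplitude, the spline loses ~1 %.
The residual amplitude bias is the 32-line boxcar window (~7 % at
100 Hz), inside the 10 % recovery tolerance; it is not deconvolved.

The vessel-orthogonal motion is `|w1| = |v|·sin θ`, θ being the
vessel-to-scan-axis angle; a warning is emitted below θ = 10° where the
projection loses sensitivity. The tremor component is isolated with a
zero-phase 4th-order Butterworth high-pass above 30 Hz. Reported
amplitude is the rectified mean times π/2 (exact for a sinusoid);
RMS·√2 and half peak-to-peak are available alternatives, since the
notion of "amplitude" for a broadband trace is a convention. Spectra
are Welch periodograms with NaN points linearly interpolated first.

## Radon velocimetry and flow

Blood cells crossing the line scan draw diagonal streaks whose slope
(px of space per line) encodes speed. Per overlapping ROI (128 lines,
50 % overlap), the dominant streak angle maximizes the standard
deviation of the 1-D projection of the rotated ROI (columns summed over
rows), searched at 1° resolution and refined by three bracketed passes
(0.25° shrinking 4× each) plus parabolic interpolation. The static
band profile is removed by subtracting column means first. Velocity is
`space_scale × line_rate × tan(angle from time axis)`, divided by
sin θ for the oblique scan geometry. ROI quality is the excess of the
winning projection STD over the same ROI with its pixels shuffled
(identical marginal statistics, no streak structure); this baseline is
immune to the interpolation-free STD spikes a rotation search exhibits
at axis-aligned angles, which defeat simpler median-based contrast
measures on pure noise. Velocities outside the 0.03–1275 mm/s
measurement bandwidth are flagged, never clipped.

Slope resolution bounds accuracy at the bandwidth extremes: a 0.1 mm/s
cell at 1 µm/px and 15 kHz is a 0.38° streak and a 1000 mm/s cell an
89.1° streak, and no angle search reaches 5 % velocity precision there
at fixed geometry. The package therefore measures multi-scale, as an
operator would zoom and window per vessel: integer time decimation
(averaging line blocks, provided by `decimate_time`) multiplies slow
slopes into the well-conditioned range, and coarser spatial sampling
does the same for fast cells. The validation sweep recovers 0.1, 1,
10, 100 and 1000 mm/s each within ~3 % under per-velocity geometry.

Lumen diameter is the full width at half maximum of a motion-contrast
profile (per-pixel temporal STD of the registered video) across the
vessel, background-subtracted (median of the outer quarters) with
linear edge interpolation. Flow is `v̄ · π(d/2)²` converted to µL/min
(µm³/s × 60/10⁹; 1 mm/s through 50 µm = 0.1178 µL/min); no
parabolic-profile correction factor is applied. Vessel populations are
summarized by least squares on `log y = log a + b log x` for the
power-law flow–diameter model `y = a·xᵇ`. Pulsation frequency is the
dominant Welch peak of the velocity series in 1–20 Hz, required to
exceed five times the in-band median power, reported in Hz and
per-minute.

## OCT boundary segmentation and thickness mapping

Boundaries are minimum-cost left-to-right paths through a pixel graph:
node gradients are the signed vertical intensity derivative normalized
to [0, 1] under the requested polarity, edge weights between
8-connected horizontally adjacent pixels are `2 − (g_a + g_b) + w_min`
with `w_min = 1e-5`, and virtual zero-cost padding columns free the
entry and exit rows. The dynamic program folds the predecessor's
gradient into the minimization (`min over prev of cost[prev] −
g[prev]`), which is required for true shortest paths; tests verify
equality with brute-force path enumeration on tiny bands. The
vitreous→ILM boundary (dark-to-bright) is found first over the full
depth; the OS-RPE boundary (bright-to-dark) is then constrained at
least 20 px below the ILM path to prevent collapse onto the same edge.
Vessel-shadow columns (mean intensity below 55 % of the column median)
are re-interpolated from neighbors and flagged invalid.

TRT = (OS-RPE − ILM) × axial scale, mapped en face. A circular region
of 8° *diameter* (the figure is read as a diameter and is configurable)
around the configured optic-disc center is masked NaN and never enters
statistics. Longitudinal change assumes grid-identical follow-up
acquisitions (instrument-side registration); the union of visit masks
applies, and change is summarized overall (µm and %) and within three
configurable eccentricity annuli about the map center.

## Gait decoding

The 256-count encoder on the 90 mm wheel is decoded at 4× resolution
(every edge) by a transition table over the two-bit gray-code state;
simultaneous two-bit transitions are illegal, counted, and warned above
1 % of transitions. Distance is `counts/(4·cpr) × π·diameter`; speed is
the per-1 s-bin displacement magnitude. Synchronization assigns each
imaging timestamp the 1 s gait bin containing it; non-overlapping
samples are missing, and zero overlap is an error.

## Synthetic data generators

All generators are pure functions of (parameters, seed) with named
per-generator RNG streams derived from one master seed; regeneration is
bit-identical. Ground truth is emitted in the units the analysis
reports.

- **Pupil scenes**: near-uniform dark ellipse on uniform-noise speckle;
  blinks darken whole frames to 30 %. The texture contrast is chosen so
  the surround's local STD sits well above 0.25 and the pupil interior
  well below.
- **SLO video**: one retina-like texture (smoothed random field plus
  dark curvilinear vessels) translated sub-pixel by the gaze trace;
  blink frames scale to 40 % of the mean.
- **Line scans**: a soft-edged dark vessel band displaced per line by
  `w1(t)/sin θ` so the generator's truth is already the orthogonal
  component; micro-tremor is white noise FFT-masked to 30–200 Hz and
  scaled to the requested RMS (default 2 µm), plus 2 Hz respiratory
  (3 µm) and 9 Hz cardiac (1.5 µm) sinusoids — the band is what awake
  recordings show, the generative form and the component amplitudes
  are this package's choices, sized to make all features visible in
  spectra and configurable. Blood-cell streaks are Gaussian capsules
  (exact point-to-segment distance in the shear-corrected band frame,
  cross-section σ = 2 px); capsule rendering matters — per-line dot
  rendering creates hard end-caps that biased fast-streak angles by
  tens of percent in validation.
- **OCT volumes**: sigmoid-edged retina slab between a smoothly sagging
  ILM and an OS-RPE offset by the thickness map, bright RPE band,
  multiplicative speckle.
- **Encoder**: position integrated from the speed profile, emitted as
  quadrature square waves; an aliasing guard requires the sample rate
  to be at least 20× the edge rate.

What the generators do **not** emulate: optical point-spread and
aberrations, photon-calibrated noise, eyelid/eyelash occlusion
geometry, vessel wall pulsation, hematocrit-dependent streak contrast,
curved OCT geometry or real speckle statistics, and encoder contact
bounce. Passing recovery tests therefore demonstrates correctness of
the algorithms under controlled conditions, not performance parity on
animal recordings.

## Problem sizes and validation scale

Desk-scale defaults keep every check fast while preserving the
governing ratios (strip width vs. tremor band, ROI length vs. streak
slope, depth sampling vs. thickness): line scans of 2–32 k lines,
videos of 6–30 frames at 160–256 px, OCT volumes of 4–8 B-scans, 20
seeded volumes for the thickness-recovery study, n = 50 vessels for
the power-law fit. The acceptance script recomputes all headline
quantities from scratch at these sizes in about a minute.

## Known limitations

- The strip-level boxcar window attenuates tremor amplitude by ~7 % at
  100 Hz; amplitudes are reported unadjusted.
- Strip registration estimates pure translation per strip; rotation and
  within-strip shear are not modelled.
- Radon velocimetry reports speed magnitude; flow direction is taken
  from geometry, not the streak sign convention.
- The DP path moves at most one row per column; boundaries steeper than
  45° per pixel column (rare in retinal OCT at usual aspect ratios)
  would be tracked lagged.
- Longitudinal OCT change requires grid-identical visits; no inter-visit
  registration is implemented.
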