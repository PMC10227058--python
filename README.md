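# awake-retina

Analysis pipeline for high-resolution retinal imaging in **awake,
head-fixed mice**. Removing general anesthesia preserves the eye's
natural physiology — fixational eye motion, single-cell blood flow,
retinal thickness — but leaves the recordings contaminated by blinks,
gaze shifts, beam clipping at the pupil, and a high-frequency
micro-tremor that shears scanned frames line by line. This package
implements the full measurement stack needed to quantify and correct
those effects, for experimenters running SLO/AOSLO/OCT rigs on
head-restrained mice and for anyone who needs a tested, synthetic-data-
validated reference implementation of the underlying algorithms.

## What it computes

| Stage | Module | Core method |
|---|---|---|
| Pupil stability & beam clipping | `pupiltrack` | local-STD texture filter (STD < 0.25), watershed, least-squares ellipse fit, causal jump gates, polygonal beam∩pupil overlap, 1 s binning |
| Blinks & gaze | `gazetrack` | 60 %-of-mean blink rule; three-template zero-mean NCC tracking with sub-pixel refinement; 10 s window normalization; gaze–gait Pearson R |
| AOSLO motion correction | `stripreg` | 32-line strip registration to a reference frame (NCC ≥ 0.5, σ = 5 px pre-smoothing for fluorescence), rigid frame registration baseline, registered averaging with coverage maps |
| Micro-tremor | `linescan_tremor` | 20 random reference strips, 1-D NCC shear trace, 10 px jump gate, point-wise median merge; \|w₁\| = \|v\|·sin θ; >30 Hz high-pass; Welch spectra |
| Blood flow | `hemodynamics` | Radon-style projection-STD angle search on overlapping ROIs, v = scale·rate·tan(angle); motion-contrast FWHM diameter; flow = v̄·π(d/2)² in µL/min; power-law fit y = a·xᵇ |
| Retinal thickness | `octlayers` | graph-DP shortest-path ILM / OS-RPE segmentation, TRT maps with an 8° optic-disc mask, longitudinal change by eccentricity |
| Locomotion | `gait` | 4× quadrature decoding, distance/speed in 1 s bins, timestamp synchronization |
| Synthetic truth | `synthdata` | seeded generators for every input above, emitting ground truth in analysis units |

The micro-tremor measurement is the centerpiece: scanning a 1-D beam
across a major vessel at 15 kHz records a space–time image whose band
is sheared by eye motion; the shear trace v(t), projected orthogonal to
the vessel as |w₁| = |v|·sin θ, resolves micron-scale motion in a
30–200 Hz band with respiratory (≈2 Hz) and cardiac (≈9 Hz) peaks —
motion that vanishes under ketamine/xylazine anesthesia.

## Worked example

Run the end-to-end synthetic demo (generate → analyze → report):

```bash
awake-retina run --seed 3 --out demo/
```

which prints (abridged):

```json
{
  "tremor": {
    "amplitude_um": 2.076,
    "amplitude_arcmin": 3.664,
    "band_hz": [30.0, 200.0],
    "low_freq_peaks_hz": [1.83, 9.16]
  },
  "flow": {
    "median_velocity_mm_s": 10.21,
    "flow_ul_min_40um": 0.770
  },
  "oct": {"mean_trt_um": 204.02, "truth_trt_um": 205.0},
  "gait": {"total_distance_m": 1.5998, "truth_distance_m": 1.6000}
}
```

Reading the numbers: the generator injected a 2 µm RMS band-limited
tremor plus 2 Hz / 9 Hz components, and the extracted trace returns a
2.08 µm amplitude with spectral peaks at 1.83 and 9.16 Hz (one Welch
bin from truth). Streaks drawn at 10 mm/s are measured at 10.21 mm/s;
through a 40 µm lumen that is 0.77 µL/min. The OCT volume built with a
205 µm retina measures 204.0 µm, and the encoder decode recovers the
1.600 m of simulated wheel travel to 0.2 mm.

Individual stages run on files, e.g.:

```bash
awake-retina simulate --seed 1 --what linescan --out data/
awake-retina tremor data/linescan.tif --out results/   # trace, spectrum, summary
awake-retina flow data/linescan.tif --diameter-um 40 --out results/
```

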