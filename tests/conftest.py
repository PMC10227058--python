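"""Shared fixtures: small synthetic datasets with known ground truth."""

import numpy as np
import pytest

from awakeretina import synthdata as sd


@pytest.fixture(scope="session")
def pupil_video():
    """Static centered pupil on speckle, 20 frames at 8.8 fps."""
    scene = sd.PupilScene(seed=7)
    video, truth = sd.gen_pupil_video(scene, n_frames=20, frame_rate=8.8)
    return video, truth, scene


@pytest.fixture(scope="session")
def slo_shift_video():
    """SLO video with known integer-pixel gaze steps and two blink frames."""
    deg_per_px = 0.1
    offsets_px = np.zeros((30, 2))
    offsets_px[10:] = (3.0, -2.0)
    offsets_px[20:] = (-5.0, 4.0)
    video, truth = sd.gen_slo_video(
        offsets_px * deg_per_px, deg_per_px=deg_per_px,
        blink_frames=(15, 16), shape=(192, 192), noise=0.005, seed=3)
    return video, truth


@pytest.fixture(scope="session")
def tremor_linescan():
    """Line scan with a pure 100 Hz, 4 µm orthogonal sinusoid at theta=90."""
    tm = sd.TremorModel(band_lo=30, band_hi=200, rms_amplitude=0.0,
                        resp_amp=0.0, cardiac_amp=0.0, seed=5)
    # build the sinusoid by hand via resp channel at 100 Hz
    tm = sd.TremorModel(rms_amplitude=0.0, resp_freq=100.0, resp_amp=4.0,
                        cardiac_amp=0.0, seed=5)
    st, truth = sd.gen_linescan(tm, None, n_lines=4096, n_space=128,
                                theta=90.0, noise=0.01, seed=5)
    return st, truth


@pytest.fixture(scope="session")
def oct_uniform_volume():
    """OCT volume with a uniform 200 µm thickness map, low noise."""
    tmap = np.full((8, 64), 200.0)
    vol, truth = sd.gen_oct_volume(tmap, axial_scale=2.0, depth_px=200,
                                   noise=0.02, seed=11)
    return vol, truth
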