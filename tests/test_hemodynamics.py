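"""Radon velocimetry, vessel diameter, flow conversion, and model fit."""

import numpy as np
import pandas as pd
import pytest

from awakeretina import hemodynamics as hd
from awakeretina import synthdata as sd
from awakeretina.core_io import SpaceTimeImage


def _linescan(v_mm_s, n_lines=2048, n_space=128, scale=1.0, density=2.0,
              halfwidth=20.0, seed=1, noise=0.01, theta=90.0):
    st, truth = sd.gen_linescan(
        None, sd.StreakModel(velocities=(v_mm_s,), streaks_per_ms=density,
                             band_center_px=n_space / 2,
                             band_halfwidth_px=halfwidth, seed=seed),
        n_lines=n_lines, n_space=n_space, space_scale=scale, theta=theta,
        noise=noise, seed=seed)
    return st


class TestRadonVelocity:
    def test_45_degree_streaks_give_one_px_per_line(self):
        """1 px/line at 1 µm/px and 15 kHz is 15 mm/s."""
        st = _linescan(15.0)
        res = hd.radon_velocity(st.data[:128], st)
        assert res["valid"]
        assert abs(res["velocity_mm_s"] - 15.0) / 15.0 < 0.05

    def test_isotropic_noise_roi_invalid(self):
        rng = np.random.default_rng(0)
        st = SpaceTimeImage(data=rng.uniform(size=(256, 128)))
        res = hd.radon_velocity(st.data[:128], st)
        assert not res["valid"] and np.isnan(res["velocity_mm_s"])

    def test_oblique_scan_correction(self):
        """At theta=30 the along-scan slope is divided by sin(30)=0.5."""
        st90 = _linescan(10.0, theta=90.0)
        st30 = SpaceTimeImage(data=st90.data, line_rate=st90.line_rate,
                              space_scale=st90.space_scale, theta=30.0)
        v90 = hd.radon_velocity(st90.data[:128], st90)["velocity_mm_s"]
        v30 = hd.radon_velocity(st30.data[:128], st30)["velocity_mm_s"]
        assert abs(v30 - 2 * v90) / (2 * v90) < 1e-6

    def test_bandwidth_flag_not_clip(self):
        st = _linescan(15.0)
        cfg = hd.RadonConfig(velocity_bandwidth=(0.03, 10.0))
        res = hd.radon_velocity(st.data[:128], st, cfg)
        assert res["valid"] and not res["in_bandwidth"]
        assert res["velocity_mm_s"] > 10.0

    @pytest.mark.parametrize("v,scale,decim,n_lines,n_space,hw,dens", [
        (0.1, 0.5, 32, 32768, 96, 20, 0.02),
        (1.0, 0.5, 4, 8192, 96, 20, 0.5),
        (10.0, 1.0, 1, 2048, 128, 20, 2.0),
        (100.0, 4.0, 1, 2048, 128, 30, 0.5),
        (1000.0, 8.0, 1, 2048, 192, 40, 0.2),
    ])
    def test_velocity_sweep_within_5pct(self, v, scale, decim, n_lines,
                                        n_space, hw, dens):
        """Cells at 0.1-1000 mm/s recover within 5 % when the imaging
        geometry (zoom, time decimation) is matched to the speed."""
        st = _linescan(v, n_lines=n_lines, n_space=n_space, scale=scale,
                       density=dens, halfwidth=hw)
        tc = hd.velocity_timecourse(hd.decimate_time(st, decim),
                                    hd.RadonConfig(roi_time=128))
        est = tc.loc[tc["valid"], "velocity_mm_s"].median()
        assert abs(est - v) / v < 0.05


class TestVelocityTimecourse:
    def test_series_length_formula(self):
        st = _linescan(10.0, n_lines=2048)
        cfg = hd.RadonConfig(roi_time=128, roi_overlap=0.5)
        tc = hd.velocity_timecourse(st, cfg)
        assert len(tc) == (2048 - 128) // 64 + 1

    def test_constant_velocity_flat_series(self):
        st = _linescan(10.0, n_lines=2048)
        tc = hd.velocity_timecourse(st, hd.RadonConfig(roi_time=128))
        v = tc.loc[tc["valid"], "velocity_mm_s"]
        assert v.std() / v.mean() < 0.05

    def test_pulsatile_modulation_tracked(self):
        """Streak velocity stepped 10 -> 14 -> 10 mm/s is tracked within
        5 % in each segment."""
        pieces = []
        for v in (10.0, 14.0, 10.0):
            pieces.append(_linescan(v, n_lines=2048, seed=int(v)).data)
        st = SpaceTimeImage(data=np.vstack(pieces), line_rate=15000.0,
                            space_scale=1.0, theta=90.0)
        tc = hd.velocity_timecourse(st, hd.RadonConfig(roi_time=128))
        t = tc["time_s"].to_numpy()
        seg_dur = 2048 / 15000.0
        for i, v in enumerate((10.0, 14.0, 10.0)):
            sel = (t >= i * seg_dur + 0.02) & (t < (i + 1) * seg_dur - 0.02)
            est = tc.loc[sel & tc["valid"], "velocity_mm_s"].median()
            assert abs(est - v) / v < 0.05


class TestHeartRate:
    @staticmethod
    def _series(freq_hz, fs=234.0, n=2048, depth=0.3, base=12.0, seed=0):
        t = np.arange(n) / fs
        rng = np.random.default_rng(seed)
        v = base * (1 + depth * np.sin(2 * np.pi * freq_hz * t))
        v += rng.normal(0, 0.2, n)
        return pd.DataFrame({"time_s": t, "velocity_mm_s": v,
                             "valid": np.ones(n, bool)})

    def test_2hz_reported_as_120_per_minute(self):
        out = hd.heart_rate(self._series(2.0))
        assert out["detected"]
        assert abs(out["freq_hz"] - 2.0) < 0.25
        assert abs(out["per_minute"] - 120.0) < 15.0

    def test_9hz_at_strip_sampling(self):
        out = hd.heart_rate(self._series(9.0, fs=468.0))
        assert out["detected"] and abs(out["freq_hz"] - 9.0) < 0.25

    def test_unmodulated_series_not_detected(self):
        out = hd.heart_rate(self._series(2.0, depth=0.0, seed=1))
        assert not out["detected"]


class TestVesselDiameter:
    def test_fwhm_of_synthetic_lumen(self):
        """A 40 µm lumen with soft edges measures 40 ± 2 µm."""
        x = np.arange(128, dtype=float)
        profile = 1.0 / (1.0 + np.exp(-(20.0 - np.abs(x - 64.0)) / 1.0))
        mc = np.tile(profile * 0.3 + 0.02, (16, 1))
        assert abs(hd.vessel_diameter(mc, 1.0) - 40.0) <= 2.0

    def test_px_scale_linearity(self):
        x = np.arange(128, dtype=float)
        profile = np.exp(-0.5 * ((x - 64) / 8.0) ** 2)
        mc = np.tile(profile, (4, 1))
        d1 = hd.vessel_diameter(mc, 1.0)
        d2 = hd.vessel_diameter(mc, 2.0)
        assert abs(d2 - 2 * d1) < 1e-9

    def test_motion_free_video_raises(self):
        frames = np.tile(np.random.default_rng(0).uniform(size=(32, 32)),
                         (5, 1, 1))
        mc = hd.motion_contrast(frames)
        with pytest.raises(ValueError):
            hd.vessel_diameter(mc, 1.0)

    def test_motion_contrast_highlights_moving_band(self):
        rng = np.random.default_rng(1)
        frames = np.full((20, 16, 64), 0.5)
        frames[:, :, 28:36] += rng.normal(0, 0.2, (20, 16, 8))
        mc = hd.motion_contrast(frames)
        assert mc[:, 28:36].mean() > 10 * mc[:, :20].mean()


class TestFlowRate:
    def test_hand_computed_conversion(self):
        """1 mm/s through 50 µm: π·25²·1000 µm³/s = 0.1178 µL/min."""
        assert abs(hd.flow_rate(1.0, 50.0) - 0.1178) < 1e-4

    def test_printed_reduction_worked_examples(self):
        assert round(hd.percent_reduction(1.56, 0.89)) == 43
        assert round(hd.percent_reduction(1.56, 0.66)) == 58

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            hd.flow_rate(0.0, 50.0)


class TestFlowDiameterModel:
    def test_exact_power_law_recovered(self):
        d = np.array([10.0, 20.0, 40.0, 80.0])
        rec = pd.DataFrame({"diameter_um": d,
                            "flow_ul_min": 0.002 * d**2.5})
        fit = hd.fit_flow_diameter(rec)
        assert abs(fit["a"] - 0.002) < 1e-6
        assert abs(fit["b"] - 2.5) < 1e-6

    def test_noisy_exponent_within_band(self):
        """Lognormal scatter σ=0.2, n=50: exponent recovered within ±0.2."""
        rng = np.random.default_rng(123)
        d = rng.uniform(5.0, 50.0, 50)
        y = 0.001 * d**2.8 * np.exp(rng.normal(0, 0.2, 50))
        fit = hd.fit_flow_diameter(pd.DataFrame({"diameter_um": d,
                                                 "flow_ul_min": y}))
        assert abs(fit["b"] - 2.8) <= 0.2

    def test_underdetermined_rejected(self):
        rec = pd.DataFrame({"diameter_um": [10.0, 20.0],
                            "flow_ul_min": [0.1, 0.4]})
        with pytest.raises(ValueError):
            hd.fit_flow_diameter(rec)


class TestAnesthesiaContrastFlow:
    def test_awake_exceeds_anesthetized_in_rate_and_flow(self):
        """Awake analogue (faster cells, 8 Hz pulse) vs anesthetized
        (slower, 4.5 Hz): the pipeline reproduces the ordering in both
        pulse frequency and flow."""
        results = {}
        for label, base_v, pulse_hz, seed in (("awake", 14.0, 8.0, 2),
                                              ("anesth", 8.0, 4.5, 3)):
            # modulated velocity rendered piecewise per ROI-sized block
            n_blocks = 24
            block = 256
            pieces = []
            for i in range(n_blocks):
                t = i * block / 15000.0
                v = base_v * (1 + 0.25 * np.sin(2 * np.pi * pulse_hz * t))
                st_i = _linescan(v, n_lines=2048, seed=seed * 100 + i)
                pieces.append(st_i.data[:block])
            st = SpaceTimeImage(data=np.vstack(pieces), line_rate=15000.0,
                                space_scale=1.0, theta=90.0)
            tc = hd.velocity_timecourse(st, hd.RadonConfig(
                roi_time=128, roi_overlap=0.5))
            hr = hd.heart_rate(tc)
            v_mean = tc.loc[tc["valid"], "velocity_mm_s"].mean()
            results[label] = (hr, v_mean, hd.flow_rate(v_mean, 40.0))
        hr_a, v_a, f_a = results["awake"]
        hr_k, v_k, f_k = results["anesth"]
        assert hr_a["detected"] and hr_k["detected"]
        assert hr_a["freq_hz"] > hr_k["freq_hz"]
        assert f_a > f_k
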