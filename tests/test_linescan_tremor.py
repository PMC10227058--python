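"""Shear-trace extraction, filtering, spectra, and tremor statistics."""

import numpy as np
import pytest

from awakeretina import linescan_tremor as lt
from awakeretina import synthdata as sd
from awakeretina.core_io import ScaleModel, SpaceTimeImage


class TestExtractShear:
    def test_straight_vessel_trace_near_zero(self):
        st, _ = sd.gen_linescan(None, None, n_lines=2048, noise=0.01, seed=0)
        trace = lt.extract_shear(st, seed=0)
        assert np.abs(trace.v_px).max() < 0.5  # below one-pixel noise floor

    def test_sinusoid_amplitude_and_frequency_recovered(self, tremor_linescan):
        """100 Hz, 4 µm orthogonal sinusoid: amplitude within 10 %, spectral
        peak at 100 ± 2 Hz."""
        st, truth = tremor_linescan
        trace = lt.extract_shear(st, seed=1)
        stats = lt.tremor_stats(trace, cutoff=30.0)
        assert abs(stats["amplitude_um"] - 4.0) / 4.0 <= 0.10
        freqs, power = lt.motion_spectrum(trace.w1_um, trace.sample_rate,
                                          nperseg=4096)
        peak = freqs[np.argmax(power)]
        assert abs(peak - 100.0) <= 2.0

    def test_equivariance_under_constant_shift(self, tremor_linescan):
        """Shifting the whole image by a constant column offset shifts the
        (mean-centered) trace by nothing — and the raw correlation by the
        constant, which cancels in the zero-centering."""
        st, _ = tremor_linescan
        rolled = SpaceTimeImage(data=np.roll(st.data, 3, axis=1),
                                line_rate=st.line_rate,
                                space_scale=st.space_scale, theta=st.theta)
        t1 = lt.extract_shear(st, seed=2)
        t2 = lt.extract_shear(rolled, seed=2)
        # identical up to the roll's edge effects
        corr = np.corrcoef(t1.v_px, t2.v_px)[0, 1]
        assert corr > 0.99

    def test_median_merge_breaks_down_gracefully(self, tremor_linescan):
        """Corrupting 40 % of candidate traces with gross errors leaves the
        point-wise median close to the clean trace."""
        st, _ = tremor_linescan
        clean = lt.extract_shear(st, n_refs=20, seed=3)
        profiles = lt._strip_profiles(st.data, 32)
        n_strips = profiles.shape[0]
        rng = np.random.default_rng(0)
        cands = np.empty((20, n_strips))
        for ci in range(20):
            base = clean.v_px[np.minimum(
                (np.arange(n_strips) * 32 + 16), clean.v_px.size - 1)]
            if ci < 8:  # 40% corrupted
                cands[ci] = base + rng.normal(0, 30, n_strips)
            else:
                cands[ci] = base
        med = np.median(cands, axis=0)
        ref = np.median(cands[8:], axis=0)
        assert np.abs(med - ref).max() < 1.0

    def test_too_short_image_rejected(self):
        st = SpaceTimeImage(data=np.random.default_rng(0).uniform(
            size=(256, 64)))
        with pytest.raises(ValueError):
            lt.extract_shear(st, n_refs=20, strip_lines=32)


class TestProjectOrthogonal:
    def _trace(self, v_px, theta):
        return lt.ShearTrace(v_px=np.asarray(v_px, float),
                             valid=np.ones(len(v_px), bool),
                             line_rate=15000.0, space_scale=1.0, theta=theta,
                             n_reference_strips=20, strip_lines=32)

    def test_theta90_identity(self):
        tr = lt.project_orthogonal(self._trace([1.0, -2.0], 90.0))
        np.testing.assert_allclose(tr.w1_um, [1.0, -2.0], atol=1e-12)

    def test_theta30_halves(self):
        tr = lt.project_orthogonal(self._trace([6.0], 30.0))
        np.testing.assert_allclose(tr.w1_um, [3.0], atol=1e-12)

    def test_small_theta_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="awakeretina"):
            lt.project_orthogonal(self._trace([1.0], 5.0))
        assert any("sensitivity" in r.message for r in caplog.records)


class TestHighpass:
    def test_2hz_attenuated_100hz_preserved(self):
        """Frequency response at 2 Hz < 5 % and at 100 Hz > 95 % for the
        30 Hz high-pass (verified against the analytic Butterworth response)."""
        from scipy import signal as sig

        rate = 1000.0
        t = np.arange(8192) / rate
        for f, keep in ((2.0, False), (100.0, True)):
            x = np.sin(2 * np.pi * f * t)
            y = lt.highpass(x, rate, cutoff=30.0)
            amp = np.abs(y[1000:-1000]).max()
            # analytic zero-phase (squared-magnitude) Butterworth response
            w, h = sig.sosfreqz(sig.butter(4, 30.0, "highpass", fs=rate,
                                           output="sos"), worN=[f], fs=rate)
            expected = np.abs(h[0]) ** 2
            assert abs(amp - expected) < 0.05
            assert (amp > 0.95) if keep else (amp < 0.05)

    def test_constant_trace_zeroed(self):
        out = lt.highpass(np.full(4096, 3.3), 1000.0)
        assert np.abs(out).max() < 1e-9

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            lt.highpass(np.zeros(100), 50.0, cutoff=30.0)


class TestMotionSpectrum:
    def test_respiratory_and_cardiac_peaks(self):
        tm = sd.TremorModel(rms_amplitude=1.5, resp_amp=3.0, cardiac_amp=1.5,
                            seed=6)
        trace = sd.tremor_trace(tm, 32768, 2000.0)
        freqs, power = lt.motion_spectrum(trace, 2000.0, nperseg=8192)
        peaks = lt.find_spectral_peaks(freqs, power, fmax=20.0)
        df = freqs[1] - freqs[0]
        assert any(abs(p - 2.0) <= df for p in peaks)
        assert any(abs(p - 9.0) <= df for p in peaks)

    def test_band_power_elevated_in_tremor_band(self):
        tm = sd.TremorModel(rms_amplitude=2.0, resp_amp=0.0, cardiac_amp=0.0,
                            seed=7)
        trace = sd.tremor_trace(tm, 16384, 1000.0)
        freqs, power = lt.motion_spectrum(trace, 1000.0, nperseg=4096)
        band = power[(freqs >= 30) & (freqs <= 200)].mean()
        control = power[(freqs >= 250) & (freqs <= 400)].mean()
        assert band > 10 * control

    def test_white_noise_flat_spectrum(self):
        rng = np.random.default_rng(8)
        freqs, power = lt.motion_spectrum(rng.standard_normal(16384), 1000.0)
        sel = freqs > 1.0
        slope = np.polyfit(np.log(freqs[sel]), np.log(power[sel]), 1)[0]
        assert abs(slope) < 0.1

    def test_velocity_band_near_100hz(self):
        """The velocity spectrum of 30-200 Hz band-limited motion peaks in
        the band (velocity weighting ~f pushes power toward ~100+ Hz)."""
        tm = sd.TremorModel(rms_amplitude=2.0, resp_amp=3.0, cardiac_amp=1.5,
                            seed=9)
        rate = 2000.0
        trace = sd.tremor_trace(tm, 32768, rate)
        vel = np.diff(trace) * rate
        freqs, power = lt.motion_spectrum(vel, rate, nperseg=8192)
        peak = freqs[np.argmax(power)]
        assert 30.0 <= peak <= 200.0


class TestTremorStats:
    def test_sinusoid_amplitude_identity(self):
        """Rectified mean of |A sin| is 2A/π, so the π/2 correction returns
        A within 3 %."""
        rate = 2000.0
        t = np.arange(16384) / rate
        trace = lt.ShearTrace(
            v_px=3.0 * np.sin(2 * np.pi * 80.0 * t),
            valid=np.ones(t.size, bool), line_rate=rate, space_scale=1.0,
            theta=90.0, n_reference_strips=20, strip_lines=32)
        stats = lt.tremor_stats(trace, cutoff=30.0)
        assert abs(stats["amplitude_um"] - 3.0) / 3.0 < 0.03

    def test_zero_trace_zero_amplitude(self):
        trace = lt.ShearTrace(
            v_px=np.zeros(8192), valid=np.ones(8192, bool), line_rate=2000.0,
            space_scale=1.0, theta=90.0, n_reference_strips=20, strip_lines=32)
        assert lt.tremor_stats(trace)["amplitude_um"] == 0.0

    def test_unit_conversion_to_arcmin(self):
        rate = 2000.0
        t = np.arange(16384) / rate
        trace = lt.ShearTrace(
            v_px=5.95 * np.sin(2 * np.pi * 80.0 * t),
            valid=np.ones(t.size, bool), line_rate=rate, space_scale=1.0,
            theta=90.0, n_reference_strips=20, strip_lines=32)
        stats = lt.tremor_stats(trace, scale=ScaleModel(34.0))
        assert abs(stats["amplitude_arcmin"]
                   - stats["amplitude_um"] / 34.0 * 60.0) < 1e-9
        assert abs(stats["amplitude_arcmin"] - 10.50) < 0.35


class TestAnesthesiaContrast:
    def test_zero_tremor_amplitude_below_awake(self):
        """Silencing the generator's tremor (anesthesia analogue) collapses
        the measured amplitude to the straight-vessel noise floor."""
        awake_tm = sd.TremorModel(rms_amplitude=2.0, resp_amp=3.0,
                                  cardiac_amp=1.5, seed=10)
        st_awake, _ = sd.gen_linescan(awake_tm, None, n_lines=4096, seed=10)
        st_anesth, _ = sd.gen_linescan(None, None, n_lines=4096, noise=0.02,
                                       seed=10)
        amp_awake = lt.tremor_stats(lt.extract_shear(st_awake, seed=0)
                                    )["amplitude_um"]
        amp_anesth = lt.tremor_stats(lt.extract_shear(st_anesth, seed=0)
                                     )["amplitude_um"]
        assert amp_anesth < 0.3  # noise floor, sub-pixel
        assert amp_awake > 5 * amp_anesth
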