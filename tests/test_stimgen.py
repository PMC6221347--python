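"""Stimulus synthesis: sweep endpoints, calibration, reversal, call-echo."""

import numpy as np
import pytest
from scipy import signal

from efptiming import stimgen


def ridge_track(w, f_lo=0.0, f_hi=np.inf, nperseg=256):
    """Spectral-peak frequency track of a waveform (independent of synthesis)."""
    f, t, S = signal.stft(w.samples, fs=w.sample_rate, nperseg=nperseg,
                          noverlap=nperseg - nperseg // 8)
    mask = (f >= f_lo) & (f <= f_hi)
    ridge = f[mask][np.argmax(np.abs(S[mask]), axis=0)]
    return t, ridge


class TestFmChirp:
    def test_standard_call_ridge_endpoints(self):
        """H1 of the standard call sweeps down from 55 kHz to 25 kHz."""
        spec = stimgen.StimulusSpec(duration=3e-3, harmonics=((55e3, 25e3),))
        w = stimgen.make_fm_chirp(spec)
        t, ridge = ridge_track(w)
        tol = 2 * w.sample_rate / 256
        inside = (t > 3e-4) & (t < spec.duration - 3e-4)  # skip ramp edges
        expected = stimgen.instantaneous_frequency(spec, t[inside])
        assert np.all(np.abs(ridge[inside] - expected) < tol)
        assert stimgen.instantaneous_frequency(spec, 0.0) == 55e3
        assert stimgen.instantaneous_frequency(spec, 3e-3) == pytest.approx(25e3)

    def test_degenerate_sweep_is_constant_tone(self):
        spec = stimgen.StimulusSpec(duration=3e-3, harmonics=((40e3, 40e3),),
                                    ramp_duration=0.0)
        w = stimgen.make_fm_chirp(spec)
        freqs = np.fft.rfftfreq(w.samples.size, 1 / w.sample_rate)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(w.samples)))]
        assert peak == pytest.approx(40e3, abs=freqs[1])

    def test_instantaneous_frequency_matches_phase_derivative(self):
        """Finite-difference of the analytic phase reproduces f(t) mid-sweep."""
        spec = stimgen.StimulusSpec(duration=3e-3, harmonics=((55e3, 25e3),))
        t = 1.5e-3
        h = 1e-8
        phase = lambda tt: stimgen._sweep_phase(55e3, 25e3, np.asarray(tt),
                                                3e-3, "quadratic")
        f_fd = (phase(t + h) - phase(t - h)) / (2 * h) / (2 * np.pi)
        assert f_fd == pytest.approx(
            stimgen.instantaneous_frequency(spec, t), rel=1e-6)
        # quadratic law value at mid-sweep: 25 + 30*(0.5)^2 kHz
        assert stimgen.instantaneous_frequency(spec, t) == pytest.approx(32.5e3)

    def test_harmonic2_is_twice_harmonic1(self):
        w = stimgen.make_fm_chirp(stimgen.standard_call())
        # disjoint search bands for the two ridges over the mid-sweep, where
        # H1 (25.8-45.8 kHz) and H2 (51.7-91.5 kHz) cannot be confused
        t1, r1 = ridge_track(w, 22e3, 48e3, nperseg=512)
        t2, r2 = ridge_track(w, 50e3, 95e3, nperseg=512)
        inside = (t1 > 5e-4) & (t1 < 2.5e-3)
        tol = 4 * w.sample_rate / 512
        assert np.all(np.abs(r2[inside] - 2 * r1[inside]) < tol)

    def test_rms_calibration_exact(self):
        for level in (60.0, 70.0, 75.0):
            spec = stimgen.StimulusSpec(duration=3e-3, level_db_spl=level)
            w = stimgen.make_fm_chirp(spec)
            target = 20e-6 * 10 ** (level / 20)
            assert abs(w.rms - target) / target < 1e-6

    def test_frequency_above_nyquist_names_harmonic(self):
        with pytest.raises(ValueError, match="harmonic 2"):
            stimgen.StimulusSpec(duration=3e-3,
                                 harmonics=((55e3, 25e3), (110e3, 50e3)),
                                 sample_rate=200e3)

    def test_non_positive_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            stimgen.StimulusSpec(duration=0.0)


class TestWhiteNoise:
    def test_band_limitation(self):
        w = stimgen.make_white_noise((25e3, 110e3), 3e-3, 70.0, seed=0)
        freqs = np.fft.rfftfreq(w.samples.size, 1 / w.sample_rate)
        psd = np.abs(np.fft.rfft(w.samples)) ** 2
        in_band = psd[(freqs > 30e3) & (freqs < 100e3)].mean()
        out_band = psd[np.argmin(np.abs(freqs - 10e3))]
        assert 10 * np.log10(in_band / max(out_band, 1e-300)) >= 30

    def test_zero_duration_empty(self):
        w = stimgen.make_white_noise((25e3, 110e3), 0.0, 70.0, seed=0)
        assert w.samples.size == 0

    def test_rms_matches_level(self):
        target = 20e-6 * 10 ** (70 / 20)
        rms = [stimgen.make_white_noise((25e3, 110e3), 3e-3, 70.0, seed=s).rms
               for s in range(10)]
        assert np.all(np.abs(np.asarray(rms) - target) / target < 0.05)

    def test_reproducible_and_band_checked(self):
        a = stimgen.make_white_noise((25e3, 110e3), 1e-3, 70.0, seed=3)
        b = stimgen.make_white_noise((25e3, 110e3), 1e-3, 70.0, seed=3)
        assert np.array_equal(a.samples, b.samples)
        with pytest.raises(ValueError, match="inverted"):
            stimgen.make_white_noise((110e3, 25e3), 1e-3, 70.0, seed=0)


class TestTimeReverse:
    def test_involution(self):
        w = stimgen.make_fm_chirp(stimgen.standard_call())
        assert np.array_equal(
            stimgen.time_reverse(stimgen.time_reverse(w)).samples, w.samples)

    def test_reversed_call_sweeps_upward(self):
        spec = stimgen.StimulusSpec(duration=3e-3, harmonics=((55e3, 25e3),))
        w = stimgen.time_reverse(stimgen.make_fm_chirp(spec))
        t, ridge = ridge_track(w)
        inside = (t > 5e-4) & (t < 2.5e-3)
        assert np.all(np.diff(ridge[inside]) >= 0)
        assert ridge[inside][0] < 35e3 < ridge[inside][-1]

    def test_magnitude_spectrum_preserved(self):
        w = stimgen.make_fm_chirp(stimgen.standard_call())
        r = stimgen.time_reverse(w)
        np.testing.assert_allclose(np.abs(np.fft.rfft(r.samples)),
                                   np.abs(np.fft.rfft(w.samples)),
                                   rtol=1e-9, atol=1e-12)


class TestCallEcho:
    def test_echo_level_and_onset(self):
        call_spec = stimgen.standard_call(level_db_spl=75.0)
        pair = stimgen.make_call_echo_pair(
            stimgen.CallEchoSpec(call_spec, echo_attenuation_db=10.0,
                                 echo_delay=28e-3))
        rate = pair.sample_rate
        onset = int(round(0.028 * rate))
        call = stimgen.make_fm_chirp(call_spec)
        echo_seg = pair.samples[onset : onset + call.samples.size]
        assert np.sqrt(np.mean(echo_seg**2)) == pytest.approx(
            call.rms / 10 ** 0.5, rel=1e-9)
        assert pair.samples.size == onset + call.samples.size

    def test_zero_delay_zero_attenuation_doubles(self):
        spec = stimgen.CallEchoSpec(stimgen.standard_call(),
                                    echo_attenuation_db=0.0, echo_delay=0.0)
        pair = stimgen.make_call_echo_pair(spec)
        call = stimgen.make_fm_chirp(spec.call)
        np.testing.assert_allclose(pair.samples, 2 * call.samples, atol=1e-12)

    def test_crosscorrelation_separation(self):
        """Matched-filter output shows two maxima exactly the delay apart."""
        delay = 10e-3
        spec = stimgen.CallEchoSpec(stimgen.standard_call(),
                                    echo_attenuation_db=6.0, echo_delay=delay)
        pair = stimgen.make_call_echo_pair(spec)
        call = stimgen.make_fm_chirp(spec.call)
        xc = signal.correlate(pair.samples, call.samples, mode="valid")
        lag1 = np.argmax(xc)
        xc2 = xc.copy()
        half = call.samples.size // 2
        xc2[max(0, lag1 - half) : lag1 + half] = -np.inf
        lag2 = np.argmax(xc2)
        assert abs(lag2 - lag1) == int(round(delay * pair.sample_rate))

    def test_negative_delay_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            stimgen.CallEchoSpec(stimgen.standard_call(), echo_delay=-1e-3)
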