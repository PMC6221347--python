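"""Detection pipeline: filters, thresholds, peaks, latency stats, outliers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from efptiming import sigproc
from efptiming.sigproc import BANDS, OutlierRule


def brute_force_fences(values, w):
    """Independent quartile-fence oracle: sorted-order-statistic percentiles
    with linear interpolation, written out longhand."""
    v = sorted(values)
    n = len(v)

    def pct(q):
        pos = q / 100 * (n - 1)
        lo = int(np.floor(pos))
        hi = min(lo + 1, n - 1)
        return v[lo] + (pos - lo) * (v[hi] - v[lo])

    q1, q3 = pct(25), pct(75)
    return q1 - w * (q3 - q1), q3 + w * (q3 - q1)


class TestBandpass:
    def test_passband_identity(self, fs):
        t = np.arange(int(fs)) / fs
        x = np.sin(2 * np.pi * 400 * t)
        y = sigproc.bandpass(x, BANDS["EFP_high"], fs)
        mid = slice(int(0.2 * fs), int(0.8 * fs))
        assert np.abs(y[mid]).max() == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuation(self, fs):
        t = np.arange(int(fs)) / fs
        x = np.sin(2 * np.pi * 50 * t)
        y = sigproc.bandpass(x, BANDS["EFP_high"], fs)
        mid = slice(int(0.2 * fs), int(0.8 * fs))
        assert 20 * np.log10(np.abs(y[mid]).max()) <= -40

    def test_linearity(self, fs):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal((2, 4000))
        band = BANDS["EFP_full"]
        lhs = sigproc.bandpass(a + b, band, fs)
        rhs = sigproc.bandpass(a, band, fs) + sigproc.bandpass(b, band, fs)
        # 1e-9 relative to the output scale (zero crossings need the atol)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-7,
                                   atol=1e-9 * np.abs(lhs).max())

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            sigproc.bandpass(np.zeros(100), BANDS["MUA"], 4000.0)


class TestNoiseThreshold:
    def test_zero_trace(self):
        assert sigproc.noise_threshold(np.zeros(100)) == 0.0

    def test_gaussian_median_method_near_six(self):
        """median(|N(0,1)|)=0.6745, so 6x-noise threshold -> ~6.0 on unit noise."""
        rng = np.random.default_rng(1)
        thr = sigproc.noise_threshold(rng.standard_normal(2_000_000))
        assert thr == pytest.approx(6.0, rel=0.01)

    def test_sd_method(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(500_000) * 3.0
        assert sigproc.noise_threshold(x, method="sd") == pytest.approx(18.0,
                                                                        rel=0.01)

    def test_threshold_ratio_is_about_15_db(self):
        assert 20 * np.log10(6.0) == pytest.approx(15.6, abs=0.05)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sigproc.noise_threshold(np.array([]))


class TestDetectNegativePeaks:
    def test_single_template_single_peak(self, single_spike_trace, fs):
        trace, true_t = single_spike_trace
        peaks = sigproc.detect_negative_peaks(trace, 50.0, 1e-3, fs)
        assert len(peaks) == 1
        assert peaks.times[0] == pytest.approx(true_t, abs=0.5 / fs)
        assert peaks.amplitudes[0] == pytest.approx(-100.0)

    def test_two_templates_10ms_apart(self, template, fs):
        trace = np.zeros(int(0.2 * fs))
        for start in (0.05, 0.06):
            i = int(start * fs)
            trace[i : i + template.samples.size] += 100 * template.samples
        peaks = sigproc.detect_negative_peaks(trace, 50.0, 1e-3, fs)
        assert len(peaks) == 2
        assert (peaks.times[1] - peaks.times[0]) == pytest.approx(10e-3,
                                                                  abs=1 / fs)

    def test_subthreshold_trace_empty(self, fs):
        peaks = sigproc.detect_negative_peaks(np.zeros(1000) - 0.1, 1.0, 1e-3, fs)
        assert len(peaks) == 0

    def test_refractory_suppresses_close_peaks(self, template, fs):
        trace = np.zeros(int(0.1 * fs))
        for start in (0.02, 0.0205):  # 0.5 ms apart
            i = int(start * fs)
            trace[i : i + template.samples.size] += 100 * template.samples
        peaks = sigproc.detect_negative_peaks(trace, 30.0, 2e-3, fs)
        assert len(peaks) == 1


class TestOutlierExclusion:
    def test_all_equal_nothing_removed(self):
        kept, removed, _ = sigproc.exclude_outliers(np.full(10, 3.3))
        assert removed == 0 and kept.size == 10

    def test_gross_outlier_removed_and_fences_match_oracle(self):
        values = [1.0, 2.0, 3.0, 4.0, 100.0]
        kept, removed, _ = sigproc.exclude_outliers(np.array(values),
                                                    OutlierRule(w=1.2))
        assert removed == 1 and 100.0 not in kept
        lo, hi = brute_force_fences(values, 1.2)
        expected = [v for v in values if lo <= v <= hi]
        assert sorted(kept.tolist()) == expected

    def test_default_w(self):
        assert OutlierRule().w == 1.2

    def test_fewer_than_four_passthrough_with_warning(self):
        with pytest.warns(UserWarning, match="fewer than 4"):
            kept, removed, warned = sigproc.exclude_outliers(np.array([1.0, 2.0]))
        assert warned and removed == 0 and kept.size == 2

    @given(st.lists(st.floats(-1e6, 1e6), min_size=4, max_size=60),
           st.floats(0.5, 3.0))
    @settings(max_examples=60, deadline=None)
    def test_fences_match_brute_force_oracle(self, values, w):
        kept, removed, _ = sigproc.exclude_outliers(np.array(values),
                                                    OutlierRule(w=w))
        lo, hi = brute_force_fences(values, w)
        expected = sorted(v for v in values if lo <= v <= hi)
        assert sorted(kept.tolist()) == pytest.approx(expected)
        assert removed == len(values) - len(expected)


class TestFirstPeakLatencies:
    def _peakset(self, times, fs=40e3):
        t = np.asarray(times, dtype=float)
        return sigproc.PeakSet(t, np.full(t.size, -50.0), BANDS["EFP_high"], 10.0)

    def test_constant_latency_fixture(self):
        onsets = 0.1 + 0.3 * np.arange(20)
        stats = sigproc.first_peak_latencies(self._peakset(onsets + 7.8e-3),
                                             onsets)
        assert stats.mean == pytest.approx(7.8e-3)
        assert stats.sd == pytest.approx(0.0, abs=1e-12)
        assert stats.detection_reliability == 1.0

    def test_no_peaks_marked_undefined(self):
        onsets = 0.1 + 0.3 * np.arange(5)
        stats = sigproc.first_peak_latencies(self._peakset([]), onsets)
        assert stats.detection_reliability == 0.0
        assert not stats.defined

    def test_72_of_80_is_90_percent(self):
        onsets = 0.1 + 0.3 * np.arange(80)
        stats = sigproc.first_peak_latencies(
            self._peakset(onsets[:72] + 10e-3), onsets)
        assert stats.detection_reliability == pytest.approx(0.9)

    def test_window_overlapping_next_onset_rejected(self):
        onsets = np.array([0.1, 0.13])
        with pytest.raises(ValueError, match="window overlaps"):
            sigproc.first_peak_latencies(self._peakset([0.11]), onsets,
                                         window=0.05)

    def test_first_peak_selected_not_deepest(self):
        onsets = np.array([0.1])
        peaks = sigproc.PeakSet(np.array([0.105, 0.11]),
                                np.array([-30.0, -300.0]), None, 10.0)
        stats = sigproc.first_peak_latencies(peaks, onsets)
        assert stats.mean == pytest.approx(5e-3)


class TestDetectionReliability:
    @pytest.mark.parametrize("n_hit, n_trials, expected",
                             [(72, 80, 0.9), (0, 10, 0.0), (10, 10, 1.0)])
    def test_fractions(self, n_hit, n_trials, expected):
        onsets = 0.1 + 0.3 * np.arange(n_trials)
        times = onsets[:n_hit] + 5e-3
        peaks = sigproc.PeakSet(np.asarray(times), np.full(n_hit, -50.0))
        assert sigproc.detection_reliability(peaks, onsets) == pytest.approx(
            expected)


class TestPipelineProperties:
    def test_noiseless_recovery_wideband_and_mua(self, single_spike_trace, fs):
        """First-peak latency = spike time + trough offset, spike-band exact."""
        trace, true_t = single_spike_trace
        onsets = np.array([0.08])
        for name in ("wideband", "MUA"):
            stats, _ = sigproc.analyze_band(trace, BANDS[name], onsets, fs,
                                            threshold=30.0)
            assert stats.mean + onsets[0] == pytest.approx(true_t, abs=1.5 / fs)

    def test_zero_phase_no_latency_bias_symmetric_template(self, fs):
        """Symmetric template: filtered trough identical across bands."""
        t = (np.arange(-40, 41)) / fs
        sym = -np.exp(-0.5 * (t / 0.2e-3) ** 2)
        trace = np.zeros(int(0.2 * fs))
        i0 = int(0.1 * fs)
        trace[i0 - 40 : i0 + 41] = 100 * sym
        troughs = [np.argmin(sigproc.bandpass(trace, BANDS[b], fs))
                   for b in ("wideband", "MUA", "EFP_full", "EFP_high")]
        assert max(troughs) - min(troughs) <= 1

    def test_efp_high_detects_wherever_efp_full_does(self, fs):
        """Spiking-only sources: the 200-600-Hz band is at least as prevalent."""
        from efptiming import synthrec

        cfg = synthrec.PopulationRecConfig(
            n_neurons=10,
            latency=synthrec.LatencyModel.from_uniform_window(8e-3, 1e-3),
            n_trials=30, seed=5)
        rec = synthrec.generate_recording(cfg)
        hits = {}
        for name in ("EFP_full", "EFP_high"):
            stats, _ = sigproc.analyze_band(rec.trace, BANDS[name],
                                            rec.trial_onsets, rec.sample_rate)
            hits[name] = stats.detection_reliability
        assert hits["EFP_high"] >= hits["EFP_full"]
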