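"""Readers/writers for the on-disk formats: float WAV, JSON sidecars, CSV.

Recordings are serialized as a float32 WAV (the trace, µV stored as float
samples) plus a JSON sidecar holding the sample rate, trial onsets and
ground-truth spike times.  All times on disk are seconds.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .sigproc import LatencyStats, PeakSet
from .stimgen import Waveform
from .synthrec import Recording


def write_wav(path, w: Waveform) -> None:
    wavfile.write(str(path), int(round(w.sample_rate)),
                  w.samples.astype(np.float32))


def read_wav(path) -> Waveform:
    rate, data = wavfile.read(str(path))
    return Waveform(np.asarray(data, dtype=float), float(rate))


def save_recording(rec: Recording, directory) -> Path:
    """Write trace.wav + recording.json into ``directory``; returns the dir."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    wavfile.write(str(d / "trace.wav"), int(round(rec.sample_rate)),
                  rec.trace.astype(np.float32))
    sidecar = {
        "sample_rate": rec.sample_rate,
        "trial_onsets": rec.trial_onsets.tolist(),
        "ground_truth": rec.ground_truth,
        "units": {"trace": "uV", "times": "s"},
    }
    (d / "recording.json").write_text(json.dumps(sidecar))
    return d


def load_recording(directory) -> Recording:
    d = Path(directory)
    rate, trace = wavfile.read(str(d / "trace.wav"))
    meta = json.loads((d / "recording.json").read_text())
    return Recording(np.asarray(trace, dtype=float), float(meta["sample_rate"]),
                     np.asarray(meta["trial_onsets"], dtype=float),
                     meta["ground_truth"])


def events_to_frame(peaks_by_band: dict[str, PeakSet],
                    trial_onsets: np.ndarray, window: float = 0.05
                    ) -> pd.DataFrame:
    """Tidy event table: (trial, band, peak_time_s, amplitude_uV, is_first)."""
    onsets = np.asarray(trial_onsets, dtype=float)
    rows = []
    for band, peaks in peaks_by_band.items():
        for onset_i, onset in enumerate(onsets):
            mask = (peaks.times > onset) & (peaks.times <= onset + window)
            idx = np.flatnonzero(mask)
            for rank, j in enumerate(idx):
                rows.append({"trial": onset_i, "band": band,
                             "peak_time_s": float(peaks.times[j]),
                             "latency_s": float(peaks.times[j] - onset),
                             "amplitude_uV": float(peaks.amplitudes[j]),
                             "is_first": rank == 0})
    return pd.DataFrame(rows, columns=["trial", "band", "peak_time_s",
                                       "latency_s", "amplitude_uV", "is_first"])


def stats_to_row(stats: LatencyStats) -> dict:
    """Site-summary row with report-friendly units (ms mean, µs SD)."""
    return {
        "band": stats.band.name if stats.band else "",
        "n_trials": stats.n_trials,
        "n_detected": stats.n_detected,
        "reliability": stats.detection_reliability,
        "mean_ms": stats.mean * 1e3 if stats.defined else np.nan,
        "sd_us": stats.sd * 1e6 if stats.defined else np.nan,
        "n_outliers_removed": stats.n_outliers_removed,
        "peak_amplitude_uV": stats.peak_amplitude_mean,
    }
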