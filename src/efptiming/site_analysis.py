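"""Per-site derived measures.

Links the size of the locally active population to field-potential
properties: the number of firing neurons near a site is approximated by
counting suprathreshold negative peaks of the *wideband* (20–3,000 Hz)
signal within ±3 ms of the site's mean EFP latency, and rank correlations
relate that count to EFP precision, latency and amplitude.  Sites are
classed as stimulus-selective when response probability differs by at
least 25% (or 50%) between two stimuli.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .sigproc import (BANDS, LatencyStats, bandpass, detect_negative_peaks,
                      estimate_background_noise, noise_threshold)


def count_firing_neurons(wideband_trace: np.ndarray, efp_stats: LatencyStats,
                         trial_onsets: np.ndarray, sample_rate: float,
                         half_window: float = 3e-3,
                         threshold: float | None = None,
                         refractory: float = 0.5e-3,
                         prefiltered: bool = False) -> float:
    """Mean per-trial count of wideband peaks within ±3 ms of the EFP latency.

    The ±3-ms window comfortably covers the 5-ms period of the 200-Hz
    high-pass cutoff.  Trials with zero suprathreshold peaks contribute
    zeros to the average.  ``threshold`` defaults to 6x the wideband
    background noise.
    """
    if not efp_stats.defined:
        raise ValueError("EFP latency mean is undefined; cannot centre the window")
    onsets = np.asarray(trial_onsets, dtype=float)
    x = np.asarray(wideband_trace, dtype=float)
    if not prefiltered:
        x = bandpass(x, BANDS["wideband"], sample_rate)
    if threshold is None:
        noise = estimate_background_noise(x, onsets, sample_rate)
        threshold = noise_threshold(noise, method="median")
    peaks = detect_negative_peaks(x, threshold, refractory, sample_rate,
                                  BANDS["wideband"])
    centre = efp_stats.mean
    counts = [
        int(np.sum((peaks.times >= onset + centre - half_window)
                   & (peaks.times <= onset + centre + half_window)))
        for onset in onsets
    ]
    return float(np.mean(counts))


def passes_response_screen(response_probability: float,
                           min_probability: float = 0.25) -> bool:
    """Screen applied before selectivity classification (e.g. >=5/20 responses)."""
    return response_probability >= min_probability


def selectivity_classify(response_probabilities, threshold: float = 0.25) -> bool:
    """Selective iff max - min response probability across stimuli >= threshold."""
    p = np.asarray(list(response_probabilities), dtype=float)
    if p.size < 2:
        raise ValueError("need response probabilities for at least 2 stimuli")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("response probabilities must lie in [0, 1]")
    return bool(p.max() - p.min() >= threshold)


def correlate_properties(sites: pd.DataFrame,
                         count_col: str = "firing_neuron_count",
                         pairs: tuple[str, ...] = ("sd", "mean_latency",
                                                   "amplitude")) -> pd.DataFrame:
    """Spearman rank correlations of firing-neuron count with EFP properties.

    Rank correlation is used because the relationships are monotone, not
    necessarily linear.  Degenerate (constant) columns yield NaN with
    ``defined`` False rather than an error.
    """
    if len(sites) < 10:
        raise ValueError("need at least 10 sites for property correlations")
    rows = []
    x = sites[count_col].to_numpy(dtype=float)
    for col in pairs:
        y = sites[col].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if np.unique(x[ok]).size < 2 or np.unique(y[ok]).size < 2:
            rows.append({"pair": f"{count_col} vs {col}", "rho": np.nan,
                         "pvalue": np.nan, "n": int(ok.sum()), "defined": False})
            continue
        rho, p = _stats.spearmanr(x[ok], y[ok])
        rows.append({"pair": f"{count_col} vs {col}", "rho": float(rho),
                     "pvalue": float(p), "n": int(ok.sum()), "defined": True})
    return pd.DataFrame(rows)
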