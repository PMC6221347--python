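"""Population-synchrony simulations and the amplitude / precision scaling laws.

Each simulated trial sums ``n`` identical spike templates whose firing times
are jittered around a common mean (uniformly within a synchrony window, or
with Gaussian jitter).  The summed trace is band-pass filtered into the EFP
and MUA bands and the first negative peak is detected exactly as for
recorded data, using a threshold of six times the SD of the (noise-free)
signal.  Two analytic statements describe the outcome:

* amplitude law:  the population signal amplitude grows linearly with the
  number of synchronously firing neurons, L ≈ a·n;
* precision law:  the SD of the population first-peak latency shrinks with
  the square root of the population size, σ̂ = c·σ/√n, where σ is the
  single-neuron latency SD.

``fit_power_law`` recovers the exponent and the linear amplitude
coefficient from a sweep over population sizes by least squares and reports
the adjusted r² goodness of fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .sigproc import BANDS, BandDef, design_bandpass
from .synthrec import DEFAULT_FS, LatencyModel, SpikeTemplate, biphasic_template

HIGH_SYNC_WINDOW = 1e-3  # s; "high synchrony": all neurons fire within 1 ms
LOW_SYNC_WINDOW = 10e-3  # s; "low synchrony": within 10 ms


@dataclass
class PopulationSimConfig:
    n_neurons: int = 5
    jitter_window: float = 5e-3  # s, uniform window width (None -> gaussian_sd)
    gaussian_sd: float | None = None  # s; overrides jitter_window when set
    mean_latency: float = 20e-3  # s; cosmetic, does not affect precision
    template: SpikeTemplate | None = None
    n_runs: int = 1000
    bands: tuple[str, ...] = ("EFP_full", "MUA")
    sample_rate: float = DEFAULT_FS
    trace_duration: float = 0.2  # s; long enough that the response occupies a
    # small fraction of the trace, as in recorded 300-ms trials — the adaptive
    # 6xSD threshold needs a mostly-quiet trace to sit below the trough
    threshold_k: float = 6.0
    noise_sd: float = 0.0  # template units; 0 = pure summation
    seed: int = 0

    def __post_init__(self):
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if self.gaussian_sd is None and self.jitter_window <= 0:
            raise ValueError("jitter window must be positive")
        if self.template is None:
            self.template = biphasic_template(self.sample_rate)

    @property
    def single_neuron_sd(self) -> float:
        """Latency SD of one neuron under this jitter model."""
        if self.gaussian_sd is not None:
            return self.gaussian_sd
        return self.jitter_window / math.sqrt(12.0)


@dataclass
class BandRunStats:
    """First-peak latency/amplitude distributions over runs for one band."""

    band: str
    latencies: np.ndarray  # s, nan where undetected
    amplitudes: np.ndarray  # |trough|, template units
    n_undetected: int

    @property
    def sd(self) -> float:
        v = self.latencies[np.isfinite(self.latencies)]
        return float(np.std(v, ddof=1)) if v.size > 1 else np.nan

    @property
    def mean(self) -> float:
        v = self.latencies[np.isfinite(self.latencies)]
        return float(np.mean(v)) if v.size else np.nan

    @property
    def mean_amplitude(self) -> float:
        v = self.amplitudes[np.isfinite(self.amplitudes)]
        return float(np.mean(v)) if v.size else np.nan


@dataclass
class SimResult:
    config: PopulationSimConfig
    per_band: dict[str, BandRunStats]
    spike_latencies: np.ndarray  # (n_runs, n) raw draws, for unfiltered checks


def _draw_latencies(cfg: PopulationSimConfig, rng: np.random.Generator
                    ) -> np.ndarray:
    shape = (cfg.n_runs, cfg.n_neurons)
    if cfg.gaussian_sd is not None:
        return rng.normal(cfg.mean_latency, cfg.gaussian_sd, shape)
    half = cfg.jitter_window / 2.0
    return rng.uniform(cfg.mean_latency - half, cfg.mean_latency + half, shape)


def _render_population(cfg: PopulationSimConfig, latencies: np.ndarray
                       ) -> np.ndarray:
    """Sum nearest-sample-placed templates into (n_runs, n_samples) traces."""
    fs = cfg.sample_rate
    tmpl = cfg.template.samples
    n_samples = int(round(cfg.trace_duration * fs))
    idx = np.rint(latencies * fs).astype(int)  # (runs, neurons)
    if idx.min() < 0 or idx.max() + tmpl.size > n_samples:
        raise ValueError("spike latencies fall outside the trace; "
                         "increase trace_duration or shift mean_latency")
    traces = np.zeros((cfg.n_runs, n_samples))
    runs = np.repeat(np.arange(cfg.n_runs), cfg.n_neurons)
    flat = idx.ravel()
    offs = np.arange(tmpl.size)
    np.add.at(traces.reshape(-1),
              (runs[:, None] * n_samples + flat[:, None] + offs[None, :]).ravel(),
              np.broadcast_to(tmpl, (flat.size, tmpl.size)).ravel())
    return traces


def _first_peak_per_run(filtered: np.ndarray, k: float
                        ) -> tuple[np.ndarray, np.ndarray, int]:
    """First sub-threshold trough per run; threshold = k * SD(run trace)."""
    thr = k * filtered.std(axis=1)
    lat_idx = np.full(filtered.shape[0], -1)
    amps = np.full(filtered.shape[0], np.nan)
    n_undetected = 0
    for i, row in enumerate(filtered):
        below = row < -thr[i]
        if not below.any():
            n_undetected += 1
            continue
        s = int(np.argmax(below))
        e = s + int(np.argmin(below[s:])) if not below[s:].all() else row.size
        j = s + int(np.argmin(row[s:e]))
        lat_idx[i] = j
        amps[i] = -row[j]
    return lat_idx, amps, n_undetected


def run_population_sim(cfg: PopulationSimConfig) -> SimResult:
    """Simulate ``n_runs`` population trials and detect first peaks per band.

    The per-run latency is the trough of the first excursion below
    ``threshold_k`` times the SD of the filtered signal itself (the adaptive
    rule also used on recorded data, applied to the noise-free sum).  Runs
    where nothing crosses threshold are flagged (counted), not silently
    dropped.
    """
    rng = np.random.default_rng(cfg.seed)
    latencies = _draw_latencies(cfg, rng)
    traces = _render_population(cfg, latencies)
    if cfg.noise_sd > 0:
        traces = traces + rng.standard_normal(traces.shape) * cfg.noise_sd
    fs = cfg.sample_rate
    per_band = {}
    for name in cfg.bands:
        band = BANDS[name] if isinstance(name, str) else name
        sos = design_bandpass(band, fs)
        filtered = _signal.sosfiltfilt(sos, traces, axis=1)
        lat_idx, amps, n_undet = _first_peak_per_run(filtered, cfg.threshold_k)
        lat = np.where(lat_idx >= 0, lat_idx / fs, np.nan)
        per_band[band.name] = BandRunStats(band.name, lat, amps, n_undet)
    return SimResult(cfg, per_band, latencies)


def sweep_population_size(ns, cfg: PopulationSimConfig) -> pd.DataFrame:
    """Repeat the simulation over population sizes; one row per (n, band).

    The per-n seeds are derived from ``cfg.seed`` so the whole sweep is
    reproducible and the n-values use independent draws.
    """
    ns = list(ns)
    if any(b <= a for a, b in zip(ns, ns[1:])):
        raise ValueError("population sizes must be strictly increasing")
    rows = []
    for i, n in enumerate(ns):
        sub = PopulationSimConfig(
            n_neurons=n, jitter_window=cfg.jitter_window,
            gaussian_sd=cfg.gaussian_sd, mean_latency=cfg.mean_latency,
            template=cfg.template, n_runs=cfg.n_runs, bands=cfg.bands,
            sample_rate=cfg.sample_rate, trace_duration=cfg.trace_duration,
            threshold_k=cfg.threshold_k, seed=cfg.seed + 1000 * (i + 1))
        res = run_population_sim(sub)
        for name, st in res.per_band.items():
            rows.append({"n": n, "band": name, "sd": st.sd, "mean": st.mean,
                         "amplitude": st.mean_amplitude,
                         "n_undetected": st.n_undetected,
                         "single_neuron_sd": sub.single_neuron_sd})
    return pd.DataFrame(rows)


def predict_sigma(sigma_single: float, n: int) -> float:
    """Square-root precision law: population latency SD = σ/√n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if sigma_single < 0:
        raise ValueError("sigma must be non-negative")
    return sigma_single / math.sqrt(n)


@dataclass
class ScalingModel:
    """Fitted scaling laws for one band of a population-size sweep."""

    exponent: float  # p in sd = c * n**p (square-root law predicts -0.5)
    coefficient: float  # c, seconds
    exponent_stderr: float
    gof: float  # adjusted r² of the log-log least-squares fit
    amp_slope: float  # a in amplitude = a * n (through the origin)
    amp_r2: float


def _adjusted_r2(y: np.ndarray, yhat: np.ndarray, n_params: int) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    n = y.size
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params)


def fit_amplitude_law(sweep: pd.DataFrame, band: str | None = None
                      ) -> tuple[float, float]:
    """Least-squares fit of amplitude = a·n through the origin; (a, adj r²)."""
    df = sweep if band is None else sweep[sweep["band"] == band]
    n = df["n"].to_numpy(dtype=float)
    amp = df["amplitude"].to_numpy(dtype=float)
    a = float(np.sum(n * amp) / np.sum(n * n))
    return a, float(_adjusted_r2(amp, a * n, 1))


def fit_power_law(sweep: pd.DataFrame, band: str | None = None) -> ScalingModel:
    """Least-squares fits sd = c·n^p (log-log) and amplitude = a·n.

    ``sweep`` is a table with columns n, sd, amplitude (optionally band).
    """
    df = sweep
    if band is not None:
        df = df[df["band"] == band]
    df = df.dropna(subset=["sd"])
    if df["n"].nunique() < 4:
        raise ValueError("need at least 4 distinct population sizes")
    if (df["sd"] <= 0).any():
        raise ValueError("power-law fit requires positive SDs")
    logn = np.log(df["n"].to_numpy(dtype=float))
    logsd = np.log(df["sd"].to_numpy(dtype=float))
    (p, logc), cov = np.polyfit(logn, logsd, 1, cov=True)
    gof = _adjusted_r2(logsd, p * logn + logc, 2)
    a, amp_r2 = fit_amplitude_law(df)
    return ScalingModel(float(p), float(math.exp(logc)),
                        float(np.sqrt(cov[0, 0])), float(gof), a, amp_r2)
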