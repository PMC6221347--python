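"""Synthetic multi-trial wideband extracellular recordings with ground truth.

The generator emulates the statistical structure the detection pipeline
assumes: on each stimulus presentation a population of neurons fires once,
stimulus-locked, with configurable per-neuron latency mean/SD; each spike
contributes a stereotyped negative-leading extracellular template; the sum
rides on white Gaussian background noise.  Call--echo trials add a second
locked response per neuron at a later latency.  Every spike time is stored
as ground truth, so pipeline estimates can be checked against the
parameters that produced the trace.

Amplitudes are in µV; the default sampling rate is 40 kHz (25-µs
resolution).  Spike times are drawn continuously and rendered at the
nearest sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

DEFAULT_FS = 40_000.0


@dataclass(frozen=True)
class SpikeTemplate:
    """Stereotyped extracellular spike waveform, most-negative sample = -1."""

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=float)
        m = s.min()
        if m >= 0:
            raise ValueError("template must have a negative trough")
        object.__setattr__(self, "samples", s / -m)  # trough normalized to -1
        if self.width >= 2e-3:
            raise ValueError("template width must be below 2 ms")

    @property
    def peak_offset(self) -> float:
        """Seconds from template start to the most-negative sample."""
        return float(np.argmin(self.samples)) / self.sample_rate

    @property
    def width(self) -> float:
        return self.samples.size / self.sample_rate


def biphasic_template(sample_rate: float = DEFAULT_FS,
                      neg_width: float = 0.3e-3,
                      pos_width: float = 0.5e-3,
                      pos_fraction: float = 0.45) -> SpikeTemplate:
    """Negative-leading biphasic spike built from two Gaussian lobes.

    ``neg_width``/``pos_width`` are full widths at half maximum of the
    negative trough and the positive rebound.
    """
    sd_n = neg_width / 2.355
    sd_p = pos_width / 2.355
    t0 = 3 * sd_n
    sep = 1.5 * (sd_n + sd_p)
    total = t0 + sep + 3.5 * sd_p
    t = np.arange(0.0, total, 1.0 / sample_rate)
    s = (-np.exp(-0.5 * ((t - t0) / sd_n) ** 2)
         + pos_fraction * np.exp(-0.5 * ((t - t0 - sep) / sd_p) ** 2))
    return SpikeTemplate(s, sample_rate)


def template_bank(rng: np.random.Generator, n: int,
                  sample_rate: float = DEFAULT_FS,
                  neg_width_range: tuple[float, float] = (0.2e-3, 0.4e-3),
                  pos_fraction_range: tuple[float, float] = (0.3, 0.6)
                  ) -> list[SpikeTemplate]:
    """Multi-template mode: per-neuron waveform diversity (widths, rebounds)."""
    bank = []
    for _ in range(n):
        w = rng.uniform(*neg_width_range)
        bank.append(biphasic_template(sample_rate, neg_width=w,
                                      pos_width=w * 4 / 3,
                                      pos_fraction=rng.uniform(*pos_fraction_range)))
    return bank


@dataclass(frozen=True)
class LatencyModel:
    """Stimulus-locked first-spike latency distribution of one neuron."""

    mean_latency: float  # s
    latency_sd: float  # s
    jitter_distribution: str = "gaussian"  # or "uniform_window"
    response_probability: float = 1.0

    def __post_init__(self):
        if self.latency_sd < 0:
            raise ValueError("latency_sd must be non-negative")
        if not 0.0 <= self.response_probability <= 1.0:
            raise ValueError("response_probability must lie in [0, 1]")
        if self.jitter_distribution not in ("gaussian", "uniform_window"):
            raise ValueError(f"unknown jitter {self.jitter_distribution!r}")

    @classmethod
    def from_uniform_window(cls, mean_latency: float, window: float,
                            response_probability: float = 1.0) -> "LatencyModel":
        """Uniform jitter over [mean - window/2, mean + window/2]; SD = window/sqrt(12)."""
        return cls(mean_latency, window / math.sqrt(12.0), "uniform_window",
                   response_probability)

    @property
    def window(self) -> float:
        """Width of the uniform window implied by the SD."""
        return self.latency_sd * math.sqrt(12.0)

    def draw(self, rng: np.random.Generator, size) -> np.ndarray:
        if self.jitter_distribution == "uniform_window":
            half = self.window / 2.0
            return rng.uniform(self.mean_latency - half,
                               self.mean_latency + half, size)
        return rng.normal(self.mean_latency, self.latency_sd, size)


@dataclass(frozen=True)
class SecondResponse:
    """Echo-evoked second response: another locked volley per neuron."""

    latency: LatencyModel  # measured from trial onset (not from the first spike)


@dataclass
class PopulationRecConfig:
    n_neurons: int = 5
    latency: LatencyModel | list[LatencyModel] = field(
        default_factory=lambda: LatencyModel(20e-3, 1e-3))
    template: SpikeTemplate | list[SpikeTemplate] | None = None
    amplitude_uv: float = 100.0  # trough amplitude of one spike, µV
    noise_sd: float | None = None  # µV; default amplitude_uv / 6 (15.6-dB SNR)
    sample_rate: float = DEFAULT_FS
    n_trials: int = 80
    inter_trial_interval: float = 0.3  # s
    pre_onset: float = 0.05  # s of baseline before the first onset
    seed: int = 0
    second_response: SecondResponse | None = None

    def __post_init__(self):
        if self.n_neurons < 1 or self.n_trials < 1:
            raise ValueError("need at least one neuron and one trial")
        if self.template is None:
            self.template = biphasic_template(self.sample_rate)
        if self.noise_sd is None:
            self.noise_sd = self.amplitude_uv / 6.0

    def latency_models(self) -> list[LatencyModel]:
        if isinstance(self.latency, LatencyModel):
            return [self.latency] * self.n_neurons
        if len(self.latency) != self.n_neurons:
            raise ValueError("per-neuron latency list must match n_neurons")
        return list(self.latency)

    def templates(self) -> list[SpikeTemplate]:
        if isinstance(self.template, SpikeTemplate):
            return [self.template] * self.n_neurons
        if len(self.template) != self.n_neurons:
            raise ValueError("per-neuron template list must match n_neurons")
        return list(self.template)


@dataclass
class Recording:
    """Multi-trial wideband trace plus TTL-equivalent onsets and ground truth."""

    trace: np.ndarray  # µV
    sample_rate: float
    trial_onsets: np.ndarray  # s, strictly increasing
    ground_truth: list[dict]  # per trial: {"spike_times": [...], "second_spike_times": [...]}

    @property
    def n_trials(self) -> int:
        return self.trial_onsets.size


def generate_recording(cfg: PopulationRecConfig) -> Recording:
    """Render a recording from the population model; reproducible under seed."""
    models = cfg.latency_models()
    templates = cfg.templates()
    max_tmpl = max(t.samples.size for t in templates)
    if max_tmpl / cfg.sample_rate >= cfg.inter_trial_interval:
        raise ValueError("spike template longer than the inter-trial interval")
    fs = cfg.sample_rate
    onsets = cfg.pre_onset + cfg.inter_trial_interval * np.arange(cfg.n_trials)
    n_samples = int(round((onsets[-1] + cfg.inter_trial_interval) * fs))
    rng = np.random.default_rng(cfg.seed)
    trace = (rng.standard_normal(n_samples) * cfg.noise_sd
             if cfg.noise_sd > 0 else np.zeros(n_samples))

    def place(spike_time: float, tmpl: SpikeTemplate):
        i0 = int(round(spike_time * fs))
        i1 = min(i0 + tmpl.samples.size, n_samples)
        if i0 < n_samples:
            trace[i0:i1] += cfg.amplitude_uv * tmpl.samples[: i1 - i0]

    ground_truth: list[dict] = []
    for onset in onsets:
        first_times, second_times = [], []
        for model, tmpl in zip(models, templates):
            if rng.random() < model.response_probability:
                t_spk = onset + float(model.draw(rng, ()))
                place(t_spk, tmpl)
                first_times.append(t_spk)
            if cfg.second_response is not None:
                m2 = cfg.second_response.latency
                if rng.random() < m2.response_probability:
                    t_spk = onset + float(m2.draw(rng, ()))
                    place(t_spk, tmpl)
                    second_times.append(t_spk)
        ground_truth.append({"spike_times": first_times,
                             "second_spike_times": second_times})
    return Recording(trace, fs, onsets, ground_truth)


# Default stimulus-class -> latency-model table for the duration/bandwidth
# experiment.  Values are free parameters constrained by the observed
# extremes (tens of µs for short wideband calls, ~200 µs for long narrowband
# calls) and the orderings: latency and SD grow with duration, SD shrinks
# with bandwidth.
_DURATION_MEAN_MS = {1.0: 6.0, 3.0: 7.0, 6.0: 9.0, 12.0: 12.0}
_DURATION_SD_US = {1.0: 20.0, 3.0: 35.0, 6.0: 60.0, 12.0: 100.0}
_BANDWIDTH_SD_FACTOR = {"wide": 1.0, "mid": 1.4, "narrow": 2.0}
_BANDWIDTH_MEAN_OFFSET_MS = {"wide": 0.0, "mid": 0.3, "narrow": 0.8}


def class_latency_map(stimulus_class: tuple[float, str],
                      table: dict | None = None) -> LatencyModel:
    """Latency model for a (duration_ms, bandwidth_category) stimulus class.

    Mean latency is non-decreasing in duration; latency SD is non-decreasing
    in duration and non-increasing in bandwidth.  A custom ``table`` mapping
    classes to LatencyModel overrides the defaults.
    """
    duration_ms, bandwidth = stimulus_class
    if table is not None:
        try:
            return table[(duration_ms, bandwidth)]
        except KeyError:
            raise ValueError(f"unknown stimulus class {stimulus_class}") from None
    if duration_ms not in _DURATION_MEAN_MS or bandwidth not in _BANDWIDTH_SD_FACTOR:
        raise ValueError(f"unknown stimulus class {stimulus_class}")
    mean = (_DURATION_MEAN_MS[duration_ms]
            + _BANDWIDTH_MEAN_OFFSET_MS[bandwidth]) * 1e-3
    sd = _DURATION_SD_US[duration_ms] * _BANDWIDTH_SD_FACTOR[bandwidth] * 1e-6
    return LatencyModel(mean, sd, "gaussian")
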