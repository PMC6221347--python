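"""Synthesis of echolocation-call stimuli.

Big brown bats (*Eptesicus fuscus*) emit downward frequency-modulated (FM)
calls with two harmonics.  The stimuli modelled here are short FM chirps of
controlled duration, bandwidth and sound pressure level, plus band-limited
white noise, time-reversed (upward-sweeping) calls, and call--echo pairs in
which the echo is an attenuated, delayed copy of the call.

Levels are given in dB SPL (re 20 µPa RMS); waveforms are pressure in Pa.
The quadratic sweep is parameterized as

    f(t) = f_end + (f_start - f_end) * (1 - t/T)**2

i.e. steepest at onset and flattening toward the end, which matches the
time--frequency shape of natural big-brown-bat calls.  The phase is the
analytic integral of f(t).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

P_REF = 20e-6  # reference pressure, Pa

DEFAULT_SAMPLE_RATE = 1_000_000.0  # Hz; playback-grade rate for ultrasonic chirps


def db_spl_to_pa(level_db_spl: float) -> float:
    """RMS pressure in Pa for a level in dB SPL."""
    return P_REF * 10.0 ** (level_db_spl / 20.0)


@dataclass(frozen=True)
class StimulusSpec:
    """Parametric description of an acoustic stimulus.

    ``harmonics`` lists (f_start, f_end) sweeps in Hz; for the standard call
    the second harmonic is exactly twice the first at every instant.
    """

    duration: float  # s
    harmonics: tuple[tuple[float, float], ...] = ((55_000.0, 25_000.0),
                                                  (110_000.0, 50_000.0))
    sweep_shape: str = "quadratic"  # or "linear"
    level_db_spl: float = 70.0
    kind: str = "chirp"  # chirp | noise | reversed_chirp
    noise_band: tuple[float, float] | None = None
    sample_rate: float = DEFAULT_SAMPLE_RATE
    harmonic_amplitudes: tuple[float, ...] | None = None  # relative; default equal
    ramp_duration: float = 1e-4  # raised-cosine on/off ramps; 0 disables

    def __post_init__(self):
        if self.duration <= 0 and self.kind != "noise":
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.sweep_shape not in ("quadratic", "linear"):
            raise ValueError(f"unknown sweep_shape {self.sweep_shape!r}")
        nyq = self.sample_rate / 2.0
        for i, (f0, f1) in enumerate(self.harmonics, start=1):
            if f0 >= nyq or f1 >= nyq:
                raise ValueError(
                    f"harmonic {i} ({f0:g}->{f1:g} Hz) exceeds Nyquist {nyq:g} Hz"
                )
            if f0 <= 0 or f1 <= 0:
                raise ValueError(f"harmonic {i} has non-positive frequency")

    @property
    def rms_pa(self) -> float:
        return db_spl_to_pa(self.level_db_spl)


@dataclass(frozen=True)
class CallEchoSpec:
    """A call followed by a delayed, attenuated copy (the echo)."""

    call: StimulusSpec
    echo_attenuation_db: float = 10.0
    echo_delay: float = 0.028  # s

    def __post_init__(self):
        if self.echo_delay < 0:
            raise ValueError("echo_delay must be non-negative")


@dataclass
class Waveform:
    """Rendered pressure waveform."""

    samples: np.ndarray  # Pa
    sample_rate: float  # Hz

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2))) if self.samples.size else 0.0


def _sweep_phase(f_start: float, f_end: float, t: np.ndarray, T: float,
                 shape: str) -> np.ndarray:
    """Phase (radians) of a sweep from f_start to f_end over duration T.

    quadratic: f(t) = f_end + (f_start - f_end)(1 - t/T)^2
        => integral: f_end*t + (f_start - f_end)*(T/3)*(1 - (1 - t/T)^3)
    linear:    f(t) = f_start + (f_end - f_start) t/T
    """
    if shape == "quadratic":
        integ = f_end * t + (f_start - f_end) * (T / 3.0) * (1.0 - (1.0 - t / T) ** 3)
    else:
        integ = f_start * t + (f_end - f_start) * t**2 / (2.0 * T)
    return 2.0 * np.pi * integ


def instantaneous_frequency(spec: StimulusSpec, t, harmonic: int = 1) -> np.ndarray:
    """Analytic instantaneous frequency of one harmonic at times ``t``."""
    t = np.asarray(t, dtype=float)
    f0, f1 = spec.harmonics[harmonic - 1]
    if spec.sweep_shape == "quadratic":
        return f1 + (f0 - f1) * (1.0 - t / spec.duration) ** 2
    return f0 + (f1 - f0) * t / spec.duration


def _apply_ramps(x: np.ndarray, sample_rate: float, ramp_duration: float) -> np.ndarray:
    n_ramp = int(round(ramp_duration * sample_rate))
    if n_ramp <= 0 or x.size < 2 * n_ramp:
        return x
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
    out = x.copy()
    out[:n_ramp] *= ramp
    out[-n_ramp:] *= ramp[::-1]
    return out


def make_fm_chirp(spec: StimulusSpec) -> Waveform:
    """Render a multi-harmonic FM chirp at the spec's RMS level."""
    if spec.kind not in ("chirp", "reversed_chirp"):
        raise ValueError(f"make_fm_chirp requires a chirp spec, got kind={spec.kind!r}")
    n = int(round(spec.duration * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate
    amps = spec.harmonic_amplitudes or (1.0,) * len(spec.harmonics)
    if len(amps) != len(spec.harmonics):
        raise ValueError("harmonic_amplitudes length must match harmonics")
    x = np.zeros(n)
    for (f0, f1), a in zip(spec.harmonics, amps):
        x += a * np.sin(_sweep_phase(f0, f1, t, spec.duration, spec.sweep_shape))
    x = _apply_ramps(x, spec.sample_rate, spec.ramp_duration)
    rms = np.sqrt(np.mean(x**2))
    if rms > 0:
        x *= spec.rms_pa / rms
    w = Waveform(x, spec.sample_rate)
    if spec.kind == "reversed_chirp":
        w = time_reverse(w)
    return w


def make_white_noise(band: tuple[float, float], duration: float,
                     level_db_spl: float, seed: int,
                     sample_rate: float = DEFAULT_SAMPLE_RATE) -> Waveform:
    """Band-limited Gaussian noise at the target RMS level.

    Band limiting is done in the frequency domain (hard spectral gate), so
    out-of-band leakage is limited only by the on/off transients.
    """
    lo, hi = min(band), max(band)
    if band[0] > band[1]:
        raise ValueError(f"inverted noise band {band}")
    if lo <= 0 or hi >= sample_rate / 2.0:
        raise ValueError(f"noise band {band} outside (0, Nyquist)")
    n = int(round(duration * sample_rate))
    if n == 0:
        return Waveform(np.zeros(0), sample_rate)
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    spec[(freqs < lo) | (freqs > hi)] = 0.0
    x = np.fft.irfft(spec, n)
    rms = np.sqrt(np.mean(x**2))
    if rms > 0:
        x *= db_spl_to_pa(level_db_spl) / rms
    return Waveform(x, sample_rate)


def time_reverse(w: Waveform) -> Waveform:
    """Time-reverse a waveform (downward sweep -> upward sweep)."""
    return Waveform(w.samples[::-1].copy(), w.sample_rate)


def make_call_echo_pair(spec: CallEchoSpec) -> Waveform:
    """Call at t=0 plus an attenuated copy starting at t=echo_delay."""
    call = make_fm_chirp(spec.call)
    gain = 10.0 ** (-spec.echo_attenuation_db / 20.0)
    delay_samples = int(round(spec.echo_delay * call.sample_rate))
    n = delay_samples + call.samples.size
    out = np.zeros(max(n, call.samples.size))
    out[: call.samples.size] += call.samples
    out[delay_samples : delay_samples + call.samples.size] += gain * call.samples
    return Waveform(out, call.sample_rate)


def standard_call(sample_rate: float = DEFAULT_SAMPLE_RATE,
                  level_db_spl: float = 70.0) -> StimulusSpec:
    """The standard 3-ms call: H1 55->25 kHz, H2 110->50 kHz, quadratic."""
    return StimulusSpec(duration=3e-3, level_db_spl=level_db_spl,
                        sample_rate=sample_rate)


# Stimulus battery of the duration/bandwidth experiment: first-harmonic sweeps
# by bandwidth category (second harmonic always 2x the first).
BANDWIDTH_SWEEPS = {
    "wide": (55_000.0, 25_000.0),
    "mid": (40_000.0, 25_000.0),
    "narrow": (30_000.0, 25_000.0),
}
DURATIONS_MS = (1.0, 3.0, 6.0, 12.0)


def duration_bandwidth_battery(sample_rate: float = DEFAULT_SAMPLE_RATE
                               ) -> dict[tuple[float, str], StimulusSpec]:
    """The 12-stimulus grid: 4 durations x 3 bandwidth categories."""
    battery = {}
    for dur_ms in DURATIONS_MS:
        for bw, (f0, f1) in BANDWIDTH_SWEEPS.items():
            battery[(dur_ms, bw)] = StimulusSpec(
                duration=dur_ms * 1e-3,
                harmonics=((f0, f1), (2 * f0, 2 * f1)),
                sample_rate=sample_rate,
            )
    return battery
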