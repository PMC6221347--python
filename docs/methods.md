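# Methods

This note documents the models, parameter choices and numerical decisions
behind `efptiming`, and what the synthetic-data results do and do not show
about real recordings.

## The measurement model

A stimulus presented at a TTL-marked onset evokes, at a recording site, a
volley of near-synchronous spikes from a local population. Each spike is
modelled as a stereotyped negative-leading extracellular template; the
recorded wideband trace is the linear sum of all templates plus white
Gaussian background noise. The analysis never sees the ground truth: it
band-pass filters the trace, detects negative peaks against an adaptive
threshold, and takes the **first negative peak after each onset** as the
response. The per-trial latency is that peak time minus the onset; a site's
temporal precision is the across-trial SD of the latency after outlier
exclusion.

Two scaling laws summarize why pooling helps. With `n` neurons firing one
spike each at latency jitter SD `σ`, the summed signal amplitude grows as
`L ≈ a·n`, while the latency SD of the pooled first peak falls as
`σ̂ = c·σ/√n`. The `1/√n` law is exact for the mean of the latency draws;
band-pass filtering and threshold crossing perturb it, which is why the
package *fits* the exponent from simulation sweeps instead of assuming it.

## Tunable parameters that matter

| parameter | default | notes |
|---|---|---|
| sampling rate (recordings) | 40 kHz | 25-µs resolution; sub-sample SDs remain estimable because jitter dithers the quantizer |
| stimulus synthesis rate | 1 MHz | ultrasonic chirps up to 110 kHz |
| analysis bands | 20–600, 20–200, 200–600, 600–3,000, 20–3,000 Hz | elliptic order 4, 0.1-dB ripple, 40-dB stopband, forward–backward |
| detection threshold | 6 × noise level | `6·median(|x|)/0.6745` on pooled pre-stimulus segments (onset−20 ms to onset); an SD variant (`6·SD(x)`) serves noise-free simulations |
| refractory | 2 ms (EFP bands), 0.5 ms (MUA/wideband) | ≈ half-period of the 200–600-Hz band's centre |
| response window | 50 ms after onset | must not overlap the next onset (300-ms inter-trial interval) |
| outlier rule | quartile fences, `w = 1.2` | removed counts always reported; < 4 values pass through with a warning flag |
| reliability screen | 90% | e.g. ≥ 72 detections over 80 presentations |
| trials per experiment | 80 (standard call), 30 (duration/bandwidth), 20 (call–echo) | the experimental designs being emulated |
| spike amplitude / noise | 100 µV trough, noise SD = amplitude/6 | the 6×-threshold detectability boundary (≈ 15-dB SNR, since 20·log₁₀6 ≈ 15.6) |
| synchrony windows | 1 ms (high) / 10 ms (low) | uniform jitter; SD = window/√12 (289 µs / 2.89 ms) |
| simulation runs | 1,000 per population size | SD of an SD estimate ≈ 2% at 1,000 runs |
| MI binning | 8 equal-width bins over the pooled 1st–99th percentile range | 30 trials/class cannot support finer binning |

## Stimulus synthesis

The quadratic sweep law is `f(t) = f_end + (f_start − f_end)(1 − t/T)²` —
steepest at onset, flattening toward the end, matching the spectrotemporal
shape of natural big-brown-bat calls; only the endpoints and the word
"quadratic" are fixed by the source material, so this parameterization is a
package choice. Phase is the exact integral of `f(t)`. Harmonics default to
equal amplitude (the original ratio is unstated; it is configurable).
Waveforms get 0.1-ms raised-cosine ramps (configurable, disableable) and are
scaled *after* ramping so the RMS exactly matches the dB SPL target
(RMS = 20 µPa · 10^(level/20)). White noise is band-limited by a hard
spectral gate and rescaled to target RMS. Loudspeaker equalization is out of
scope; the synthesized waveform is taken as the field signal.

## The synthetic-recording generator

The spike template is a biphasic waveform built from two Gaussian lobes
(negative FWHM 0.3 ms, positive rebound FWHM 0.5 ms at 45% amplitude),
trough-normalized; a multi-template mode draws widths and rebound fractions
from ranges to stand in for biophysical waveform diversity. Spike times are
drawn continuously and placed at the nearest sample. Each neuron fires with
its response probability at onset + latency, drawn uniformly within a
window or as a Gaussian. Call–echo trials add a second locked volley at a
later latency. Everything is reproducible from a single integer seed, and
the generator is linear: the noise-free trace equals the sum of placed
templates exactly.

The stimulus-class → latency-model table encodes the observed trends:
mean latency grows with call duration (6→12 ms) and with narrowing
bandwidth (+0–0.8 ms); latency SD grows with duration (20→100 µs base) and
scales ×1 / ×1.4 / ×2 for wide/mid/narrow bandwidth. These values are free
parameters constrained only by the reported extremes (tens of µs for 1-ms
wideband calls, ≈ 200 µs for 12-ms narrowband calls) and the orderings.

**What the generator does not emulate:** synaptic (non-spiking) EFP
sources, colored noise, electrode geometry, conduction delays, adaptation
across trials, site-to-site heterogeneity in response strength, and
response failures beyond Bernoulli thinning. Passing tests therefore show
that the *pipeline* recovers the statistical structure it assumes — not
that real tissue has that structure.

## Detection choices

Filtering is forward–backward (zero-phase): causal filtering would bias
latencies band-dependently, and for a symmetric pulse the filtered trough
is band-independent to within one sample (tested). Zero-phase filtering is
acausal, so a strong population response pulls the adaptive threshold
crossing onto its rising flank; detected population latencies are therefore
*earlier* than the single-neuron mean — an expected, reported feature of
pooled responses, not a bug. Peaks are the minima of contiguous
sub-threshold excursions, ties broken by the earliest sample; the
refractory rule keeps the earliest peak. Percentiles use linear
interpolation between order statistics; SDs use the n−1 denominator.
Detection timing at 15-dB SNR carries a noise-induced jitter floor of a few
tens of µs, visible in the shortest-duration stimulus classes.

The quartile fences (`w = 1.2`) are tight for Gaussian jitter: they trim
genuine tails and shrink a Gaussian SD by ≈ 7% (fences at ±2.29σ). For
bounded (uniform-window) jitter they remove nothing. This is inherent to
the quartile-fence rule itself, not an implementation artifact; recovery tests
calibrated on uniform jitter recover the configured SD to < 1%.

## Population-size simulations

Each run sums `n` identical templates jittered uniformly within the
synchrony window (mean latency 20 ms — cosmetic), renders 200 ms of trace,
filters per band, and detects the first trough below six times the SD of
the filtered signal itself — the same adaptive rule used on recorded data,
applied to the noise-free sum. The 200-ms trace length keeps the response a
small fraction of the trace so the threshold sits below the trough; with
short traces the low-synchrony response (spread over 10 ms) fails to cross
its own 6×SD threshold. Runs where no excursion crosses are flagged and
counted, never silently dropped. Global-minimum detection was considered
and rejected: the global trough of a multiunit-band sum wanders across the
jitter window, so multiunit precision would never improve with `n`,
contradicting the behavior this simulation is meant to exhibit.

Under high synchrony the fitted EFP exponent is ≈ −0.46 to −0.48 with
adjusted r² ≈ 0.997 (the filter and threshold perturb the ideal −0.5);
amplitudes are exactly linear in `n` at zero jitter (superposition) and
nearly so with jitter. The printed reference outcomes at n = 50 (≈ 75-µs
precision, ≈ 2.5-mV amplitude) depend on the unspecified absolute template
scale; this package treats only the *ratios* to the single neuron
(≈ 4× precision, ≈ 32× amplitude) as meaningful calibration references.

## Mutual information

Plugin MI is computed from the stimulus-class × latency-bin histogram. The
sample-size correction subtracts the first-order bias
`(occupied_joint − occupied_rows − occupied_cols + 1)/(2N ln 2)`
(Treves–Panzeri/Miller–Madow family); the estimated bias is clipped at zero
so correction never raises the estimate, and corrected MI is floored at 0
for reporting (the raw value is kept). A shuffle-null subtraction is
available as an alternative strategy. The exact correction and bin count
used originally are not recoverable, so results are always reported with
the estimator and bin settings attached. With the default class table the
four durations are fully separable (means ≈ 1 ms apart, SDs ≤ 200 µs) and
MI saturates at the 2-bit ceiling in every bandwidth category; the
bandwidth ordering of information emerges only when class separability
degrades, which the test suite exercises by scaling class-conditional SDs.

## Echo-delay estimation

Per trial, the first response is the earliest in-window peak and the second
is the earliest peak more than 2 ms later (the shortest tested echo delay;
the pairing rule used originally is unstated). The delay estimate is the
mean of per-trial differences after outlier exclusion; constant latency
shifts common to both responses cancel exactly. Conditions enter the
precision census only at ≥ 90% paired-detection reliability. Delays shorter
than the filtered response duration (≈ 2–4 ms) put the echo response on the
tail of the call response; such fusion-regime conditions are estimated but
biased, consistent with overestimation at short delays.

## Problem sizes

Default suite and drivers use: 1,000 runs per population size for the
scaling sweep (5 sizes × 2 synchrony regimes), 80/30/20 trials for the
standard-call, duration/bandwidth and call–echo designs, and 300 trials for
SD-recovery calibration. These sizes keep Monte-Carlo error well below the
effects being measured (e.g. SE of an SD ≈ 4% at 300 trials).

## Known limitations

- Absolute amplitudes are in arbitrary-scaled µV; no electrode/biophysics
  forward model is included, so in-vivo absolute values (minimum SDs,
  selectivity percentages, census fractions) are out of reach by design.
- The first-peak detector assumes negative-leading responses.
- The census precision floor tracks the detection-noise jitter (tens of µs
  at 15-dB SNR), so sub-100-µs conditions require higher SNR than the
  generator default.
- Bias-corrected MI remains an estimator; at 30 trials/class its residual
  bias is below ≈ 0.03 bits in the independence tests, not zero.
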