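# efptiming

**Microsecond-precision stimulus timing from synchronous population firing.**

When many neurons fire in tight synchrony after a sensory event, their summed
extracellular signature — the stimulus-evoked extracellular field potential
(EFP, analyzed here at 20–600 Hz, with the 200–600-Hz sub-band reflecting
mostly spiking) — marks the event's time far more precisely than any single
neuron can. This package implements the full computational chain used to
study that effect in the auditory midbrain (inferior colliculus) of
echolocating big brown bats:

1. **Stimulus synthesis** (`efptiming.stimgen`): two-harmonic quadratic
   downward FM chirps (the "standard call": 3 ms, H1 55→25 kHz, H2
   110→50 kHz, 70 dB SPL), band-limited white noise, time-reversed calls,
   and call–echo pairs.
2. **Synthetic recordings** (`efptiming.synthrec`): multi-trial 40-kHz
   wideband traces built from stimulus-locked spike templates with
   configurable per-neuron latency mean/SD, background noise, and ground
   truth for every spike.
3. **Detection pipeline** (`efptiming.sigproc`): zero-phase elliptic
   band-pass filters (EFP 20–600, sub-bands 20–200 / 200–600, MUA 600–3,000,
   wideband 20–3,000 Hz), an adaptive threshold at six times the background
   noise level (`6·median(|x|)/0.6745`), first-negative-peak latencies per
   trial, quartile-fence outlier exclusion (`w = 1.2`), and detection
   reliability.
4. **Population-synchrony simulations** (`efptiming.popsim`): summed-template
   populations under high (1-ms) vs low (10-ms) synchrony, and the two
   scaling laws — amplitude `L ≈ a·n` and latency precision
   `σ̂ = c·σ/√n` — recovered by least squares with adjusted-r² goodness of
   fit.
5. **Information analysis** (`efptiming.infomi`): sample-size-corrected
   Shannon mutual information between stimulus class and binned response
   latency.
6. **Echo-delay estimation** (`efptiming.echodelay`): paired first/second
   EFP latencies per trial, their difference as the delay estimate, and a
   precision census across stimulus conditions.

Per-site derived measures (firing-neuron counts, selectivity, property
correlations) live in `efptiming.site_analysis`; `efptiming.runner` and the
`efptiming` CLI tie the chain together.

## Worked example

```python
import numpy as np
from efptiming import synthrec, sigproc, popsim

# 80 trials, 20 neurons firing within a 1-ms window, 15-dB SNR
cfg = synthrec.PopulationRecConfig(
    n_neurons=20,
    latency=synthrec.LatencyModel.from_uniform_window(8e-3, 1e-3),
    n_trials=80, seed=1)
rec = synthrec.generate_recording(cfg)
stats, _ = sigproc.analyze_band(rec.trace, sigproc.BANDS["EFP_high"],
                                rec.trial_onsets, rec.sample_rate)
print(f"reliability {stats.detection_reliability:.2f}, "
      f"SD {stats.sd*1e6:.0f} µs")
# -> reliability 1.00, SD 95 µs        (single-neuron jitter SD: 289 µs)

print(round(popsim.predict_sigma(100e-6, 1000) * 1e6, 1))
# -> 3.2   (µs: the square-root law for 1,000 neurons of 100-µs jitter)
```

The detected population SD (95 µs) is ~3× smaller than the 289-µs jitter of
any single neuron — the precision gain that synchrony buys. The analysis
drivers under `analysis/` run the full studies and write tables under
`results/`:

```bash
python analysis/01_synthesize_stimuli.py        # stimulus WAVs + table
python analysis/02_standard_call_pipeline.py    # detection pipeline demo
python analysis/03_population_scaling.py        # scaling laws (Eq. fits)
python analysis/04_duration_bandwidth_information.py
python analysis/05_echo_delay.py                # delay census
```

For example, `03_population_scaling.py` prints a fitted high-synchrony EFP
exponent of −0.462 with goodness of fit 0.999 (square-root law predicts
−0.5), while low-synchrony populations show no comparable precision gain.

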