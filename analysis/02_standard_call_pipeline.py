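"""Standard-call experiment: synthetic population recording plus the full
band-split detection pipeline.

Generates 80 presentations of a 20-neuron synchronous response (1-ms
uniform jitter window, 15-dB SNR), detects first negative peaks in the
field-potential and multiunit bands, and writes the per-band site summary.
The headline observation: the 200-600-Hz band recovers the response with a
latency SD several times smaller than the per-neuron jitter SD (289 µs),
because synchronous spiking pools into one sharp field-potential trough.
"""

import pandas as pd

from efptiming.runner import RunConfig, run_experiment

out = run_experiment(RunConfig("standard_call", seed=1,
                               out_dir="results/standard_call"))
summary = pd.read_csv(out / "site_summary.csv")
print(summary.to_string(index=False))

efp = summary[summary.band == "EFP_high"].iloc[0]
print(f"\n200-600-Hz EFP: reliability {efp.reliability:.2f}, latency "
      f"{efp.mean_ms:.2f} ms, SD {efp.sd_us:.0f} µs "
      f"(single-neuron jitter SD: 289 µs).")
print("The EFP first peak leads the 8-ms single-neuron mean: the adaptive "
      "threshold crosses on the rising flank of the pooled response, so "
      "population responses are both earlier and more precise than single "
      "neurons.")
print(f"Bundle in {out}/ (events.csv has every detected peak per trial).")
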