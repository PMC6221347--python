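"""Duration/bandwidth experiment: latency precision by stimulus class and
the information carried by the latency code.

Runs the 4-duration × 3-bandwidth stimulus grid (30 trials per class),
recovers per-class first-peak latency statistics in the 200-600-Hz band,
and computes the bias-corrected mutual information between stimulus
duration and response latency within each bandwidth category.  Expected
outcome: latency SD grows with call duration and shrinks with bandwidth.
Because the default class means sit ~1 ms apart while SDs stay below
~200 µs, the four durations are fully separable and the latency code
saturates the 2-bit ceiling in every category; bandwidth differences in
information appear only when class separability degrades (see the
information-module tests for that regime).
"""

import pandas as pd

from efptiming.runner import RunConfig, run_experiment

out = run_experiment(RunConfig("duration_bandwidth", seed=3,
                               out_dir="results/duration_bandwidth"))

summary = pd.read_csv(out / "class_summary.csv")
piv = summary.pivot(index="duration_ms", columns="bandwidth", values="sd_us")
print("recovered latency SD (µs) by stimulus class:")
print(piv[["wide", "mid", "narrow"]].round(1).to_string())

mi = pd.read_csv(out / "mutual_information.csv").set_index("bandwidth")
print("\ncorrected mutual information about call duration (bits):")
print(mi["mi_corrected"].round(3).to_string())

best = summary.loc[summary.sd_us.idxmin()]
worst = summary.loc[summary.sd_us.idxmax()]
print(f"\nMost precise class: {best.duration_ms:g}-ms {best.bandwidth} "
      f"({best.sd_us:.0f} µs); least precise: {worst.duration_ms:g}-ms "
      f"{worst.bandwidth} ({worst.sd_us:.0f} µs). Short-duration classes "
      "sit near the detection-noise floor of a few tens of µs, so their "
      "bandwidth ranking can swap at 30 trials.")
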