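"""Simulate one wearable recording session through the acquisition chain.

Three postures held 10 s each at 50 Hz: strain deforms the gauge, its
resistance falls (inverse piezoresistivity), the voltage-divider reading
rises, and the firmware reports 10-bit counts smoothed by a trailing 2-s
rolling average.
"""

import numpy as np

from piezopose import NoiseConfig, default_plan, simulate_session

trace = simulate_session(default_plan(), noise=NoiseConfig(seed=1))
print(f"{len(trace)} samples over {trace.t[-1]:.2f} s")
for label in ("normal", "slight_hunchback", "severe_hunchback"):
    counts = trace.counts[trace.labels == label][150:]  # past ramp + warm-up
    print(f"  {label:<17} counts {counts.mean():6.1f} +/- {counts.std():4.1f} "
          f"(range {counts.min()}-{counts.max()})")
# Counts rise with hunchback severity: more back strain -> lower sensor
# resistance -> a larger share of the supply across the fixed divider leg.
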