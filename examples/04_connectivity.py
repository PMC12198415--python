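"""Detect a monosynaptic connection from a cross-correlogram.

Builds a presynaptic train and a postsynaptic train that receives 30%
probabilistic transmission at 2 ms latency, then applies the
hollow-Gaussian-baseline CCG test: at least two consecutive bins in the
+1.2 to +4 ms window above the 99.9% Poisson quantile, and a causal peak
exceeding the anti-causal one.
"""

import numpy as np

from dgsomi.connectivity import cross_correlogram, detect_connection
from dgsomi.synth import inject_synapse

rng = np.random.default_rng(0)
pre = np.sort(rng.uniform(0, 600, 3000))
post_background = np.sort(rng.uniform(0, 600, 3000))
post = inject_synapse(pre, post_background, efficacy=0.3, latency_ms=2.0,
                      jitter_ms=0.2, rng=rng)

ccg = detect_connection(cross_correlogram(pre, post))
print(f"connected: {ccg.connected}")
print(f"latency: {ccg.latency_ms:.2f} ms")
print(f"causal peak {ccg.causal_peak_count} vs anti-causal "
      f"{ccg.anticausal_peak_count} counts")
print(f"significant bins at lags (ms): "
      f"{[round(l, 2) for l in ccg.significant_lags_ms]}")

# and a control pair with no synapse
ccg0 = detect_connection(cross_correlogram(pre, post_background))
print(f"independent control pair connected: {ccg0.connected}")
# The detected latency matches the injected 2 ms transmission delay; the
# independent pair shows no causal peak above its co-modulation baseline.
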