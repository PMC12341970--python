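"""Frequency-dependent coupling shapes slow-wave synchrony of bursters.

Two two-compartment bursting neurons (intrinsic burst frequencies 10%
apart) are coupled between their slow compartments.  The junction either
is constant or follows the band-pass profile Gc(f) = 2.625*Gbar*
(exp(-0.1 f) - exp(-5 f)) peaking near 0.80 Hz.  Synchrony is the squared
correlation of the slow (81 ms moving average), fast (remainder) and full
waveforms over a 15 s window.  The sweep takes a few minutes.
"""

import numpy as np

from ecres import bursting

c1, c2 = bursting.default_pair()
trace = bursting.simulate_pair(c1, c2, gc_ns=20.0)
r = bursting.synchrony(trace, 20.0)
print(f"single run at 20 nS: network f = {r.network_freq_hz:.3f} Hz, "
      f"R2 slow/fast/full = {r.r2_slow:.3f}/{r.r2_fast:.3f}/{r.r2_full:.3f}")

print("\nnetwork-frequency sweep, resonant junction (Gbar = "
      f"{bursting.STUDY_GBAR_NS} nS):")
df = bursting.frequency_sweep(
    bursting.GcModel("resonant", gbar_ns=bursting.STUDY_GBAR_NS),
    bursting.STUDY_KAPPA_GRID,
)
print(df[["network_freq_hz", "gc_ns", "r2_slow", "r2_fast"]].round(4).to_string(index=False))

print("\ncoupling-strength sweep (constant junction):")
dg = bursting.gc_sweep(np.array([0.0, 5.0, 20.0, 40.0]), kappa=1.4)
print(dg[["gc_ns", "r2_slow", "r2_full"]].round(4).to_string(index=False))
# Slow-wave synchrony is highest where the network frequency meets the
# junction's resonance and falls toward both band ends; spike-level
# synchrony stays near zero throughout; with a constant junction,
# synchrony simply grows with coupling strength.
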