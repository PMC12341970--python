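"""Build the standard ZAP chirp command and inspect its frequency track.

The chirp sweeps 0.1-4 Hz exponentially over 100 s with two lead-in
cycles at the lowest frequency, the protocol used to probe membrane and
coupling resonance in a single trial.
"""

import numpy as np

from ecres import stimulus
from ecres.io import write_trace_csv

params = stimulus.current_zap(i_max=3.0)
trace = stimulus.generate_zap(params)

print(f"sweep rate L            : {params.sweep_rate:.5f} 1/s")
print(f"f at t=0 / t_max        : {stimulus.instantaneous_frequency(params, 0.0):.2f}"
      f" / {stimulus.instantaneous_frequency(params, params.t_max):.2f} Hz")
print(f"f at mid-sweep          : {stimulus.instantaneous_frequency(params, 50.0):.3f} Hz"
      f"  (geometric mean = {np.sqrt(0.1 * 4):.3f})")
print(f"chirp cycles            : {stimulus.total_cycles(params):.1f}")
print(f"total duration          : {trace.duration:.1f} s "
      f"({params.n_precycles} pre-cycles + {params.t_max:.0f} s chirp)")
print(f"current range           : {trace['I'].min():.2f} .. {trace['I'].max():.2f} nA")

write_trace_csv(trace, "zap_command.csv")
print("command written to zap_command.csv (time:s, I:nA)")
# The exponential sweep spends equal time per octave, so the low end of
# the band is probed as densely as the high end.
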