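"""Full measurement pipeline on a synthetic dual recording.

A surrogate experiment (coupled linear resonators, ZAP current into the
prejunctional cell, realistic recording noise) is generated with known
ground truth, then pushed through the spectral-ratio estimator and the
sixth-degree polynomial resonance fit -- exactly what one would do with a
real recording.
"""

from ecres import profile
from ecres.io import write_summary_json
from ecres.synth import SyntheticExperimentSpec, generate_experiment

spec = SyntheticExperimentSpec(seed=42)  # defaults: 0.1-4 Hz, 100 s, 3 nA, 20 nS
trace, truth = generate_experiment(spec)
print(f"trace: {trace.n_samples} samples at {1 / trace.dt:.0f} Hz, "
      f"channels {sorted(trace.channels)}")

profs = profile.coupling_profiles(trace, spec.zap())
for q in ("Zpre", "Zpost", "CC"):
    s = profile.fit_resonance(profs[q])
    norm = profile.normalize_profile(profs[q])
    print(f"{q:5s} f_res = {s.f_res:5.3f} Hz (truth {truth.f_res[q]:5.3f})   "
          f"peak = {s.peak:7.4f}   resonance power = {norm.amplitude.max():.3f}")

write_summary_json(profile.fit_resonance(profs["CC"]), "cc_resonance.json")
print("CC summary written to cc_resonance.json")
# The estimated resonance frequencies land within a few percent of the
# generator's ground truth despite 0.2 mV / 0.02 nA recording noise; the
# normalized peak ("resonance power") is the peak-to-baseline ratio.
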