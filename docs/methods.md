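# Methods

This note documents the models, estimators and numerical choices behind
`ecres`, the assumptions they rest on, and what the synthetic-data tests
do and do not establish.

## ZAP stimulus

The chirp is defined by its accumulated phase
`φ(t) = 2π f_lo (e^{Lt} − 1)/L`, `L = log(f_hi/f_lo)/t_max`, so the
instantaneous frequency `φ'(t)/2π = f_lo e^{Lt}` runs exactly from `f_lo`
to `f_hi`. Defaults follow the recording protocol: 0.1–4 Hz over 100 s,
two lead-in cycles at the starting frequency spliced with continuous
phase and slope, 0.1 ms sample interval (10 kHz digitization). Voltage
commands start with phase offset π so the command begins exactly at the
holding potential and the clamp sees no onset step; current commands use
the same convention with `offset = amplitude = I_max/2`, giving a purely
depolarizing 0..I_max sweep that drives the membrane from its holding
range upward (the protocol's stated voltage excursion, about −60 to
−30 mV, then emerges from the cell's input resistance). A decreasing
(`sweep="down"`) chirp is provided; its frequency track is the time
reversal of the rising one.

## Profile estimation

All measured quantities are magnitude ratios of discrete Fourier
transforms of mean-subtracted channels, evaluated on the rFFT grid
restricted to the swept band. A chirp concentrates its energy along the
sweep, so the plain DFT ratio is well conditioned there; grid points
where the denominator falls below 1e−6 of its band maximum are masked. A
moving-average smoothing over a 0.05 Hz window is applied to the ratio
before peak fitting. The analysis segment runs from chirp onset (the
lead-in cycles are excluded — they exist to shed transients) to the end
of the recording; synthetic recordings therefore include a 2 s
post-stimulus tail at baseline, as a real acquisition would, which
captures the response ring-down and keeps the estimator accurate to the
top of the band (without the tail, truncation alone costs ~2.5% at
4 Hz; with it the noiseless error is below 0.2%).

Resonance is summarized by a least-squares sixth-degree polynomial in
frequency (linear Hz grid, no regularization); the resonance frequency
and amplitude are the location and value of the fitted curve's global
maximum on the closed band, found from the real roots of the derivative
with ties broken toward lower frequency. A maximum on a band endpoint is
flagged "no interior resonance". The fitted value at the lowest band
frequency (0.1 Hz) stands in for the zero-frequency response;
`normalize_profile` divides by the profile's lowest-frequency amplitude
so a normalized peak reads as resonance power. On smooth profiles the
degree-6 fit biases peak location by up to ~1%, which bounds the
noiseless recovery accuracy.

Classical step estimates are ordinary least-squares slopes of per-step
steady-state means (final half of each step, small guard margins):
`V_post` vs `V_pre` for CC, `I_post` vs `V_pre` for G_c. Clamp currents
follow the amplifier convention (positive current opposes depolarizing
junctional inflow), so the G_c slope is negated to report a positive
conductance.

## Linear resonator theory

The "linear resonator" is the two-variable linearized membrane
`C dV/dt = −g_leak V − g_res w + I`, `τ dw/dt = V − w` (deviations from
rest), with impedance `Z(f) = 1/(g_leak + iωC + g_res/(1 + iωτ))`.
Stability (eigenvalues in the left half plane) is enforced at
construction. `design_resonator(f_res, z_peak)` inverts the map
numerically, pinning `τ = 1/(2π f_res)` so the restorative variable turns
over on the resonant cycle and solving for `(g_leak, g_res)` in log
space; the canonical test pair has resonances at 0.9 and 1.3 Hz with
equal 12 MΩ peaks — resonance frequencies and input resistances in the
range reported for pyloric pacemaker somata.

Coupled profiles use the closed forms quoted in the README; peak
localization scans 1000 log-spaced frequencies and refines with bounded
scalar minimization, ties toward lower frequency (profiles flatten near
the peak at strong coupling). A frequency-dependent junction is treated
quasi-statically: `G_c(f)` is substituted pointwise into the closed
forms. The default inverted-U scale is the bursting-study band-pass shape
normalized to 1 at its own peak; an alternative normalization at the top
band edge supports comparisons that hold the junction fixed at the band
edge while letting it rise in the middle.

Direct time-domain simulations of the same linear systems (state-space
`scipy.signal.lsim`) serve as the independent oracle for the closed forms
and as the linear generator of synthetic recordings.

## Conductance-based cells

Cells are single compartments with Hodgkin–Huxley currents
`I = ḡ m^p h^q (V − E)`; every steady-state curve is a logistic in
voltage and every voltage-dependent time constant has the form
`τ(v) = τ0 + τ1/(1 + e^{(v − v_τ)/k_τ})`, which covers constants, curves
proportional to the gate's own steady state (the Ca inactivation τ and
h-current activation τ are read this way — the self-referential reading
is the only one that needs no undefined symbols), and independent
logistics. The resonator cell (C = 2 nF; leak 98 nS at −60 mV; Ca 100 nS
at +120 mV, m³h; h-current 60 nS at −20 mV, m²) resonates near 1.3 Hz at
~13 MΩ; a variant with leak 107.8 nS, 1.8× slower Ca inactivation and
slower h-current activation shifts the resonance to ~0.97 Hz at the same
peak. A third, distinct resonator (leak/Ca/slow-K/modulatory-inward)
models an unclamped pacemaker-type neighbour.

Integration is fixed-step RK4 at dt = 0.05 ms (0.01 ms for networks
containing spiking axon compartments), gates initialized at steady state
for the initial voltage and clipped to [0, 1] against roundoff;
convergence is tested by halving dt (< 0.01 mV change). Voltage clamp is
ideal: a clamped compartment's voltage follows its command exactly and
the reported clamp current is the current-balance residual
`C dV_cmd/dt + ΣI_ion + ΣG_c(V − V_j)`; no electrode or series-resistance
model is included. Protocol runs prepend a 5 s settling period at the
stimulus baseline before the lead-in cycles. The three-cell voltage-clamp
circuit defaults to 20 nS for both junctions — the one coupling value the
modeling protocols state — and the third cell defaults to the distinct
third resonator, with an identical-cells configuration equally supported.

## Ball-and-stick cables

Each neuron is a 100 µm spherical soma plus a 1000 µm neurite in 101
compartments (uniform 10 µm, or tapering linearly 20 → 0.5 µm), with
R_m = 10 kΩ·cm², R_a = 100 Ω·cm, C_m = 1 µF/cm². Membrane conductances
follow compartment areas; axial conductances between neighbouring
midpoints use the frustum formula `g = π d_a d_b/(4 R_a ℓ)`. The gap
junction joins the *same* compartment index of two identical cables
(true conductance 100 nS by default; results are reported as attenuation
ratios, so this choice is immaterial to the qualitative claims). Both
somas are clamped; the passive problem is linear, so steady states come
from a direct nodal solve rather than time stepping, verified against
the sealed-end analytic solution `cosh((L−x)/λ)/cosh(L/λ)` to < 2%.

The resonant variant distributes the resonator channel set over all
compartments at densities scaled by area relative to the 2 nF reference
cell, and evaluates the apparent `G_c(f)` from the quasi-active
(linearized at −60 mV) complex admittance network solved per frequency.
The discretized cable is numerically stiff (sub-microsecond axial/
capacitive time constants against multi-second sweeps), so a
frequency-domain solve of the linearized system — exact in the
small-signal regime these clamp protocols probe, and reducing to the
passive solve at f = 0 — is the appropriate tool; the observed
frequency dependence is weak (peak-to-flat < 1.05 at mid-neurite).

## Bursting pair

Each burster is a soma/neurite (SN) compartment (2 nF; leak 95 nS at
−63 mV; low-threshold inactivating Ca 70 nS at +60 mV, m³h) joined by a
130 nS axial conductance to an axon compartment (250 pF; leak 5 nS; Na
3 µS with instantaneous m³ activation, h with τ = 2 ms; delayed-rectifier
K 0.5 µS, m⁴). The printed current-balance equations carry ionic terms
with signs that are inconsistent with `I = ḡm^p h^q(V−E)` as written; the
standard stable convention `C dV/dt = −ΣI_ion − I_axial(out) + I_inj` is
used. Cell 2 differs from cell 1 by the b₁ = −0.0282679 mV shift of the
SN Ca gating voltages, exactly as printed, plus a multiplicative scaling
of the SN Ca time constants; the scaling was calibrated once, to 1.167,
so the isolated burst frequencies differ by 10% under the standard
measurement protocol (25 s runs, burst onsets counted over the analysis
window), yielding 1.105 Hz and 0.992 Hz. The a₁ and c₁ scaling fields
are retained in the cell description but have no printed insertion point
in the equations and are not applied.

Runs are 25 s of RK4 at dt = 0.01 ms, both cells starting from identical
initial conditions (−60 mV, gates at steady state). Waveforms are
recorded at 1 kHz; the Slow waveform is an 81 ms centred moving average
(applied before windowing so no filter edge enters the analysis), Fast is
the pointwise remainder, and all synchrony measures are squared Pearson
correlations of the two SN voltages over a 15 s window ending 1 s before
the run end. Network frequency is the mean of the two cells' slow-wave
burst-onset rates (upward crossings of the mid-range threshold).

The band-pass junction `G_c(f) = 2.625·Ḡ_c(e^{−0.1f} − e^{−5f})` peaks at
`ln 50/4.9 ≈ 0.798 Hz` with peak value ≈ 2.37·Ḡ_c; the printed scaling
factor is implemented verbatim, and an opt-in renormalization divides by
the realized peak for the reading in which `G_c` equals `Ḡ_c` at
resonance. The stated peak position (0.75 Hz) and the printed formula's
actual peak (0.80 Hz) disagree slightly; the formula wins. Within a run
the junction is quasi-static: `G_c` is fixed at the profile value at the
network's own frequency, found by fixed-point iteration (simulate →
measure frequency → update; 1% relative tolerance, ≤ 5 iterations —
convergence typically takes 2–3).

Network frequency is swept by time-dilating the whole SN compartment:
capacitance and gating time constants are multiplied together by a
factor κ. This is an exact time rescale of the slow subsystem, so with a
constant junction the synchrony measures are nearly frequency-invariant
(the required control: slow R² varies by ~7% of its mean across
0.30–1.5 Hz), while scaling the gating time constants alone distorts the
relative coupling strength and confounds the sweep. The study defaults —
Ḡ_c = 2 nS for the resonant junction, the constant control at the
resonant profile's realized peak (4.75 nS), κ ∈ {0.7, 1.0, 1.4, 2.0,
2.8, 3.6} — place the pair in the partially synchronized regime
(slow R² ≈ 0.4–0.5) where the junction's frequency dependence visibly
modulates synchrony; with much stronger coupling synchrony saturates and
the modulation disappears.

Spike-level (Fast) synchrony is essentially absent in this architecture
— the junction couples the slow compartments, and spikes are generated
in the axons — so Fast R² sits below 0.01 with large *relative* scatter
around its near-zero mean. Statements about spike synchrony being
"unaffected" are therefore meaningful in absolute terms (variation
< 0.01) but not as a fraction of the mean.

## Synthetic data and what the tests show

The generators emulate the two protocols exactly (current-clamp ZAP into
the prejunctional cell; dual voltage-clamp with the command on V_pre and
the partner held at −60 mV) using either the linear pair (ground truth
from closed forms) or the conductance-based pair (ground truth from the
same pipeline run noiseless). Noise is additive Gaussian, default 0.2 mV
on voltages and 0.02 nA on currents (plausible sharp-electrode noise;
chosen for the synthetic study, not taken from any recording), plus an
optional 0.01 Hz sinusoidal drift, all under one seed. The recovery
suite reports bias and RMSE of resonance frequency and peak over
replicate experiments; at 5% relative voltage noise the membrane
resonance frequency is recovered within 10% RMSE.

These tests establish that the estimators are unbiased and stable on
systems satisfying their assumptions — linearity or weak nonlinearity,
stationary junctions, ideal clamp, additive stationary noise. Real dual
recordings add electrode series resistance and capacitance neutralization
artifacts, non-stationary drift, spike contamination when Na currents are
not blocked, and animal-to-animal parameter spread; passing these tests
does not certify performance under those conditions.

## Numerical conventions

Units are mV, ms, nF, µS (1/µS = MΩ), nA throughout the simulators;
public constructors take conductances in nS where the model tables are
stated that way. Degenerate inputs are rejected with named errors:
non-uniform time bases, masked normalization baselines, fewer fit points
than the polynomial needs, unstable linear parameter sets, non-symmetric
coupling matrices, time constants that go non-positive in the
physiological voltage range. Integration failures report the first
offending time.
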