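# Methods

This note records the model, the numerical choices, and the synthetic
study conditions implemented in `epifield`, in enough detail to judge
what a passing test suite does and does not demonstrate.

## Model and time units

The Epileptor field model is integrated in milliseconds of model time
with Heun's method at Δt = 0.2 ms; all public APIs speak seconds
(1 s = 1000 model units).  This convention is validated internally: with
τ_s = 5.88 the unconnected node discharges at 7.6–8.5 Hz at seizure
onset (the theta–alpha rhythm) and with τ_0 = 20000 a seizure lasts a
few tens of seconds.

Default constants: τ_s = 5.88, τ_0 = 20000, τ_2 = 100, τ_12 = 100,
I_1 = 3.1, I_2 = 0.45, a_12 = 3, γ_12 = 10, γ_22 = 1, θ_11 = θ_12 = −1,
θ_22 = −0.5, b = 1 mm, u0_ez = −1.8, u0_surround = −2.3.  The memory
time constant τ_12 deserves a remark: it is weakly constrained — the
critical excitability is insensitive to it over 10–200 — and 100 is
kept, matching the classic Epileptor's memory decay rate of 0.01 per
unit time.  The Heaviside gate is closed at threshold: S(θ, θ) = 1.

The memory integral g is carried as a sixth state variable,
`dg/dt = a_12 u1 + γ_12 (w ∗ S(u1, θ_12)) − g/(τ_s τ_12)`, which is the
exact differential form of its defining convolution.

### Regime boundaries

Two boundaries characterise the unconnected node and are recomputed by
`scripts/acceptance.py`:

- **u0_crit ≈ −2.062** — classification by simulation: integrate 60 s
  from the resting state, discard 30 s of transient, call the node
  oscillatory if the late-window u1 amplitude exceeds 1e-3; bisect to a
  bracket width of 1e-3.  At the fixed point the (u1, u2, v) block is
  decoupled from the intermediate variables (f1 does not involve q1 for
  u1 < 0), which is why this boundary is independent of τ_2 and τ_12.
- **u0_ms ≈ −3.025** — the fast subsystem's bistable/monostable
  boundary.  The two dynamically slow variables, v (timescale τ_s τ_0)
  and q2 (timescale τ_s τ_2), are frozen at their fixed-point values and
  the remaining (u1, u2, q1, g) subsystem is tested for a coexisting
  seizure oscillation.  Two numerical facts shape the protocol: the
  oscillation's basin of attraction is extremely thin away from the
  attractor, so the frozen v is ramped adiabatically (0.004 per second
  of model time) from a seizure working point to its target before a
  30-s hold is evaluated; and near its disappearance the oscillation
  approaches a homoclinic connection, so persistence is detected by
  discharge peaks (u1 > 0) in the late hold window, not by an amplitude
  threshold (the amplitude stays large while the period diverges).  The
  subsystem's oscillation dies at v = 4.10, independent of the
  integration step down to dt = 0.02 ms.

Freezing q1 as well (leaving only the planar (u1, u2) system) destroys
the oscillation far earlier, at v ≈ 3.1 (u0 ≈ −2.33); the intermediate
variable's fast participation is essential to the bistability that makes
surrounding tissue recruitable.

### Onset frequency

The discharge rate of a supercritical node chirps: 7.6 Hz for the first
cycle, ~18 Hz averaged over the first two seconds, ~29 Hz in the mature
seizure.  `onset_oscillation_frequency` therefore reports the mean rate
of the first three discharge cycles (upward zero crossings of u1) after
onset — the frequency *at* onset — rather than a periodogram peak over a
longer window, which would report the middle of the chirp.

## Geometry and geodesics

Per-vertex areas are one third of the incident triangle areas; vertex
normals are area-weighted means of incident face normals ("weighted
average" is otherwise unspecified, and area weighting is the common
choice).  Patch extraction keeps vertices within 15 mm of any contact
and then the largest edge-connected component.

Geodesic distances are graph shortest paths.  The bare edge graph
overestimates distances by up to ~8% on regular grids (metric stretch
does not vanish with refinement), which would bias the coupling-kernel
mass by ~8–10%; the default backend therefore augments the graph with 3
evenly spaced points per edge, all pairs connected by straight segments
within each face (a Steiner-point approximation), bringing the stretch
below 1.4% and the discrete kernel mass at interior vertices of a flat
sheet to 1.003.  The edge-graph backend remains available
(`method="graph"`) and is what the vertex-path operations use, since
they must return actual mesh vertices.

The kernel `w_ij = α e^{−d_ij/b} A_j` (α = 1/2πb², with the self term
α A_i) is truncated at 6b, where the missing planar mass is
1 − e^{−6}·7 ≈ 1.7%.  No renormalisation is applied at patch
boundaries: tissue outside the patch simply contributes nothing,
consistent with treating the exterior as unexcitable.

## Field integration

Heun integration exploits that the Heaviside gates flip only a few
times per discharge cycle: the coupling sums `W @ S` are maintained
incrementally by adding or subtracting a column of W whenever a vertex
crosses a threshold, which is exact and replaces two sparse
matrix-vector products per stage.  The integrator requires
θ_12 = θ_11 (true for the stated constants) so both u1-gated terms share
one gate.  Divergence (|u1| > 50) aborts with a timestamp.  With all
coupling constants zero every vertex reproduces the scalar node's
trajectory bit-for-bit (same arithmetic, same stepper).

Convergence is checked on the observables that remain well-defined
across a saddle-node onset: halving Δt moves recruitment times by < 10
ms and signal envelopes by < 1% RMS.  Raw traces are *not* comparable
pointwise across Δt — the onset time's infinite sensitivity misaligns
the spike trains — which is why the convergence test is phrased this
way.

## Synthetic study conditions

The surrogate sheets share a (l + 2m) × 2m = 58 × 30 mm planform
(electrode span l = 28 mm, margin m = 15 mm, 9 contacts at 3.5 mm
pitch).  The flat sheet sits 1.47 mm from the electrode.  The sine sheet
is the height field z = A sin(2π(x − x0)/l) with A = 7.89 mm and the
phase x0 chosen half a pitch past the first contact so that no contact
sits at a zero crossing of the fold (closest surface approach > 3 mm);
the electrode threads the folds on the mid-width line at z = 0.  The
gyral sheet is a seeded band-limited Gaussian height field (white noise
smoothed at fold_wavelength/4 = 6.25 mm, RMS height fold_amplitude/2 =
4 mm), a stand-in for a realistic folded patch.  The epileptogenic zone
is a 5-mm geodesic disc centred on the vertex nearest the innermost
contact (seizures propagate mesial → lateral, as on the modelled
electrode).

Default mesh resolution is 0.4 mm edges; the test suite and the
acceptance script run at 0.8–1.0 mm, which resolves the b = 1 mm kernel
adequately while keeping a full spread simulation under half a minute.
Problem sizes are stated in each test.

**Coupling calibration.**  A γ_11 value tuned for one kernel
discretisation does not transfer to another, so γ_11 is always
recalibrated by the sweep → velocity → interpolation procedure (`spread_velocity_sweep` on a 40 × 20 mm strip with a 10-mm
epileptogenic band, probes 10 and 30 mm beyond its edge;
`calibrate_gamma11` interpolates to a target slow-front velocity).  Two
regimes are worth noting: a planar front propagates for γ_11 ≳ 0.35
(at ~1 mm/s), but *igniting* a front from a 5-mm disc requires more
coupling (critical-radius effect), γ_11 ≳ 0.6 on the 0.8-mm mesh.  The
reference condition used for calibration is a first-to-last contact
onset delay of 4.5 s over the 28-mm span — a clinically plausible TAA
propagation delay — giving a 6.2 mm/s target and γ_11 ≈ 0.79.

**Reference recordings.**  The synthetic "observed" SEEG is the full
simulate → project → bipolar chain plus seeded white sensor noise.
Noise is specified in absolute signal units; note the central bipolar
pairs of the flat geometry are near-cancellation residuals a factor
~30 below the strongest channel, so noise above ~2% of the global peak
amplitude buries them.

## Estimators

**Onsets** use the standard envelope recipe (third-order Butterworth,
0.2 Hz high-pass, rectify, 0.6 Hz low-pass, 20% of the envelope maximum)
with zero-phase filtering so the detector is unbiased by filter delay;
the envelope maximum is taken over the full analysis window supplied by
the caller.  Undetected channels are flagged, never zero-filled.

**Fast-wave speed** shifts the source traces of 30 uniformly spaced
vertices on the innermost→outermost geodesic path by d_g/u over a
50–1000 mm/s grid (200 points) and maximises the mean pairwise Pearson
correlation.  Two measures protect the estimate: traces are high-pass
filtered at 2 Hz (zero phase) before correlation, because the slow
post-onset amplitude ramp correlates at *any* shift and otherwise drags
the optimum to a grid edge; and the 1-s analysis window is taken
shortly after the *whole patch* is recruited — earlier windows still
carry the slow recruitment-front phase gradient (the estimator then
reports the front velocity), later windows decohere as each vertex's
discharge chirp advances at its own age.  Among a few candidate offsets
after full recruitment the most phase-coherent window whose estimate is
not saturated at a grid edge is used; edge saturation and low
correlation are flagged on the estimate itself.

**Identifiability experiment.**  A reference recording generated on one
surrogate (with sensor noise) is scored against candidate simulations on
all surrogates by onset RMSE/MAE and envelope-mean correlation, each
candidate's γ_11 calibrated so its expected first-to-last delay matches
the reference (the per-surface geodesic span divided by the reference
delay).  With the default seeds the generating surface wins every
metric by a wide margin.

## Limitations

The synthetic conditions omit much of real data: no volume-conduction
from unmodelled structures (e.g. hippocampus), no electrode bending, no
1/f background or artefacts in the sensor noise, no realistic cortical
curvature statistics beyond the gyral stand-in, and the "observed"
recording is generated by the same model family that fits it — the
identifiability result therefore demonstrates sensitivity of the
sensor-space fit to geometry, not correctness of the Epileptor model
for clinical data.  The fast-wave estimate on the coarse flat surrogate
is window-sensitive (roughly 140–440 mm/s across adjacent coherent
windows); it is reported with its correlation and saturation flags and
interpreted only against the physiological 100–1000 mm/s band.  The
spectral flattening display uses a 1-s window with 90% overlap, chosen
for ~1 Hz resolution at the 256 Hz sampling rate.
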