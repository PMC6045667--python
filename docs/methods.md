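# Methods

This note records the models behind `ceamri`, the parameters that matter,
the numerical choices, and what the synthetic experiments do and do not
establish.

## Signal model and units

All RF signals are complex baseband envelopes at the proton Larmor carrier
(γ/2π = 42.577 MHz/T); the carrier itself is never synthesized. Amplitudes
are in arbitrary voltage units; one configurable scale (Hz of nutation per
unit amplitude) stands in for coil efficiency, which has no published value
for this class of setup. Gradients are in mT/m, positions in m, times in s.

The concurrently acquired spin signal is modeled as the causal discrete
convolution of the transmit envelope with the ensemble FID,

    s_MR[n] = Σ_m h[m] · u_Tx[n−m],
    h[m]    = Σ_i M0_i · exp(−m·dt/T2*_i) · exp(+j2π(γ̄ (G·r_i) M1(m·dt) + δf_i m·dt)),

with M1 the exact trapezoidal gradient moment (linear ramp then plateau).
This linear-response picture is exact for a constant gradient and a small
flip angle; the ramp makes it an approximation, which is how the acquisition
is treated throughout. The per-isochromat Bloch integrator
(`spin_sim.bloch_simulate`, Rodrigues-rotation steps with transverse decay
applied per sample, refusing steps with >0.5 rad of rotation) is the
independent oracle: at 1 µs sampling and ≤0.5° effective flip the two agree
to ≈1% relative RMS, limited by the midpoint-rule discretization
O(off-resonance·dt) rather than by flip-angle nonlinearity. Because that
floor is flat in amplitude, the convolution-fidelity ladder (error
decreasing monotonically with pulse amplitude) is demonstrated at 5–40°
flips where nonlinearity dominates.

## Pulses

* **rect** — constant envelope; the 4 ms calibration pulse.
* **chirp** — linear sweep −BW/2…+BW/2 with the envelope ramped by a
  quarter-period sine over the first and last 10% of the duration (the
  exact "sinusoidal" window shape is not published; a sine ramp is
  adopted). Imaging default: 4.1 ms, 16 kHz sweep, 8 µs sampling.
* **HS8** — AM(τ) = sech(β·τ⁸), FM ∝ ∫AM² dτ scaled to the total sweep;
  β fixed by a 1% edge truncation (sech β = 0.01). τ is sampled at
  midpoints so the envelope is exactly even. Phase always accumulates by
  trapezoidal integration of the instantaneous frequency — no closed form
  exists for the HS8 phase.

## Analog front end

The chain is linear: lossless directional coupler (amplitude ratio
c = 0.28), voltage-controlled phase shifter, voltage-controlled attenuator,
power-combiner subtraction. Device physics is reduced to transfer curves:

* **phase shifter** φ(V) = 280°·atan(V/v₀)/atan(12/v₀), v₀ = 4 V — a
  monotone, saturating curve matching the published anchors (280° coverage
  on 0–12 V, slope decreasing with voltage); insertion loss fixed at
  0.8 dB. The measured curve between anchors is not tabulated anywhere, so
  any monotone saturating shape is equally defensible; the arctangent is
  chosen for smoothness.
* **attenuator** — 1.3 dB at 6 V, linear at 1.2 dB/V down to 3 V, then a
  quadratic continuation matched in value and slope at the knee and pinned
  to 30 dB at 0 V (published: only "the slope is higher" below 3 V).
* **coupling channel** — leakage amplitude 10^(−geometric/20)·A_cpl with a
  30 dB geometric-decoupling default (consistent with ~60 dB from analog
  cancellation alone summing to ~90 dB total), an arbitrary coupling phase,
  and an optional linear off-resonance slope (dB/kHz, deg/kHz) applied per
  instantaneous-frequency bin — a one-parameter stand-in for the measured
  frequency dependence of the isolation.

## Feedback calibration

The objective is the mean magnitude of the first N received samples of a
4 ms rectangular calibration acquisition (a complex mean could cancel
spuriously). "Gradient descent" on a scalar objective is realized as
coordinate descent with sign probing; one iteration = one objective
evaluation = one simulated calibration acquisition. Schedule: phase passes
at 0.3 V then 0.1 V, attenuation at 0.05 V then 5 mV, then alternating
refinement passes with steps halved to a 5 mV floor.

During refinement the voltage step is scaled by (slope at the shallow
anchor)/(local slope) of the actuator curve — the "variable voltage step
sizes" a controller needs on a strongly nonlinear phase curve. Fixed 5 mV
steps on the steep end of the arctangent would quantize the phase at ~0.14°
and cap the analog stage near 52 dB; slope-adaptive steps hold the phase
increment at ~0.03° everywhere, which is what lets the stage reach the
60+ dB regime the hardware achieves. Thresholds are specified as total
isolation in dB and converted internally to an objective amplitude using
the known leakage level of the simulation.

Load changes are modeled as closed-form jumps of (A_cpl, φ_cpl) sized so
the objective at the current canceller setting rises by a prescribed
amount (0.05–0.15 V on a scale where the uncancelled leakage is ≈1 V);
directions that would leave the shifter's 280° coverage are redrawn so the
perturbed channel remains recoverable. The monitor loop re-runs the
calibration from the current setting whenever the objective exceeds the
threshold; re-calibrations start near the optimum and need fewer
iterations than the initial one.

## Digital cancellation

**Chirp path.** The residual leakage after analog cancellation is modeled
as (piecewise-linear signed amplitude in time, one segment per side of the
sweep center, shared intercept) × (pick-up-coil trace normalized to unit
peak) × exp(j·quadratic(t)). Implementation choices that matter:

* the amplitude is fitted to the *coherent* profile
  Re[s·conj(phase reference)], not to |s| — a magnitude fit transfers the
  MR envelope into the leak model and is destructive for leak-free data;
* the quadratic phase is estimated from the angle of the *squared*,
  smoothed product s·conj(PUC): the usual post-calibration residual is
  V-shaped with a zero crossing at the calibrated frequency, and squaring
  removes the π step so the signed amplitude can carry the flip;
* fits use only the flat part of the envelope, away from the smoothing
  window's reach of the edges and the center kink, and are sharpened by a
  Tukey-bisquare IRLS loop; the fitted model is evaluated and subtracted
  over the *entire* envelope support, because leakage left uncorrected at
  the tapered pulse edges lands in the ill-conditioned directions of the
  later deconvolution and is amplified there.

**HS8 path.** λ(t) = u_Tx(t)·(a₂t² + a₁t + a₀)·e^{jθ₀} with complex
coefficients, fitted by simulated annealing (geometric cooling T←0.95T,
2000 evaluations, Gaussian proposals scaled to parameter magnitudes,
mandatory seed) and finished by one exact least-squares solve of the
coefficients at the best θ₀ — with complex coefficients the model is linear
given the phase constant, so the polish attains the global optimum the
annealer approaches.

**Identifiability, and the calculated-MR reference.** A 6-parameter
modulated-copy model cannot distinguish residual leakage from the part of
the MR signal whose modulation is equally smooth: the quadratic phase can
re-chirp the reference onto any single FID tone, and each spin packet's
sweep crossing is intrinsically slow (Fresnel width √(T/BW) ≈ 0.5 ms
here). The absorbed fraction is proportional to the MR signal at *any*
MR-to-leakage ratio, so a blind per-spoke fit removes a substantial part
of smooth-phantom signal no matter how the levels are set. Both fitters
therefore accept an optional `mr_reference` — a calculated spin response
(convolution model or Bloch) of an assumed object; the leak model is then
fitted to the difference trace and only the fitted leakage is subtracted.
This is the automated counterpart of manually refining the fit against a
computed MR signal, which is how this class of processing is used in
practice; the blind path remains available and its absorption behavior is
exercised directly in the test suite.

## Reconstruction

`U` is the lower-triangular Toeplitz operator of the pulse (n×L). The
default solve is a rank-tolerant pseudo-inverse (singular values below
machine-eps × σ_max × max dimension discarded, with a warning on rank
deficiency); Tikhonov λ ≥ 0 is available because the chirp operator's
condition number grows quickly with L (≈10⁴ at n = 512, L = 128) and any
non-convolutional contamination — receiver noise included — is amplified
by small-σ modes. The FID length is picked by an RMSE elbow: the candidate
*before* the first relative improvement under 1%.

For one-sided FID spokes of a real object the antipodal spoke's |h| equals
the spoke's own, so the sub-sample center-shift correction cross-correlates
the pair magnitudes *unreversed* (reversal is the two-sided-spoke
convention and degenerates for FIDs); the parabolic-interpolated peak lag
is the differential timing error, half of which is removed from each spoke
as a linear spectral phase. A common delay of both spokes is unobservable
from the pair and is left alone. On ideal data the estimator returns
exactly zero.

Gridding: radial density compensation |k|^(d−1)·Δk with the actual
per-sample Δk of the ramped trajectory; Kaiser-Bessel kernel of width 4 on
a 2×-oversampled grid with the standard Beatty β; forward FFT (the FID
model encodes positions with a +j phase); closed-form deapodization;
central crop; magnitude output. Sample m sits at k((m+0.5)·dt), which
fixes the sign conventions. 2D is first-class so the full pipeline runs in
seconds; 3D shares the code paths with a deterministic spherical-spiral
ordering built from antipodal pairs (their mean direction is exactly
zero). An optional `skip_initial` drops the innermost k-space samples — the
usual central-gap situation of FID-based radial imaging.

## Phantoms and protocols

* `tubes` — eight disks on a ring (T2\* 5 ms) plus two smaller tubes with
  shorter T2\* (2 and 1 ms), echoing a doped-solution structure phantom.
* `fe-series` — six vials with 1/T2\* = r₂\*·C for C ∈ {20, 29, 38, 56,
  71, 100} mM and r₂\* = 250 s⁻¹mM⁻¹, spanning T2\* ≈ 40–200 µs.
* `point`, `two-disk` — test objects; the two-disk phantom uses T2\* =
  100/70 µs so the FID fits inside the deconvolution window
  (e^{−L·dt/T2\*} < 10⁻⁴ at L = 128 — a longer tail would alias through
  the ill-conditioned solve).
* `desk-2d` — 128 spokes × 512 samples, 4.1 ms smoothed 16 kHz chirp,
  2.35 mT/m with a 50 µs ramp, FOV 0.24 m. The gradient is set so
  k(L·dt) equals the grid Nyquist radius for a 48² matrix. `desk-3d` and
  `phantom-3d` scale the same machinery to 3D.

Disk phantoms are isochromat grids at FOV/96 spacing; the discrete lattice
creates spectral replicas at the lattice frequency, identical in any image
and its analytic reference, so comparisons are unaffected.

## End-to-end imaging experiment

The two-disk demonstration (`scenarios.two_disk_imaging_demo`): a channel
with a (−0.05 dB/kHz, 0.3°/kHz) off-resonance slope is auto-calibrated to
92 dB total isolation on the rectangular pulse, then detuned by 0.9 dB in
amplitude to emulate coupling drift between calibration and scan; the MR
signal is scaled 10 dB above the resulting residual leakage; acquisition
is noiseless so the experiment isolates the systematic leakage path
(receiver noise through the unregularized pseudo-inverse is a separate
effect, controlled by λ). With the calculated-MR-assisted chirp
cancellation the corrected reconstruction lands at ≈0.06 normalized RMS
image error against the leakage-free analytic reference (least-squares
intensity matching; the reference shares the FID truncation and gridding
of the pipeline under test).

## Known limitations

* The convolution model ignores T1, steady-state saturation and the
  ramp-time violation of time invariance; all are small at sub-degree
  flips and the short readouts used here.
* Blind digital cancellation is net-destructive for smooth, low-resolution
  objects (see identifiability above) — the reference-assisted path is the
  supported route for image-quality work.
* The feedback loop's wall-clock timing (50 ms cycles), receiver
  saturation, vendor integration, S-parameter-level frequency response,
  B1 maps, flow and acoustic effects are out of scope; spokes acquired
  during re-calibration are flagged, not re-acquired.
* Actuator curves between the published anchor points are modeling
  choices; only the anchors (280° / 0–12 V, 1.3 dB at 6 V, 1.2 dB/V on
  3–6 V, 0.8 dB insertion loss, c = 0.28) are data.
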