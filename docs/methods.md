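# Methods

`spiralpc` re-creates, end to end and without a scanner, a free-breathing
real-time phase-contrast MRI (RT-PCMR) experiment of the kind run on
mid-field (0.55 T) systems with moderate gradients: a dual-density
golden-angle spiral readout, SENSE-based compressed-sensing reconstruction,
phase-contrast velocimetry, and beat-to-beat flow quantification. This note
records the models, the numerical choices, and what the synthetic data can
and cannot show.

## Trajectory design

One spiral-out interleaf is designed under hardware limits (defaults
26 mT/m amplitude, 45 T/m/s slew). The radial sampling density is
prescribed as a multiple of the Nyquist arm spacing 1/FOV: 2.0x over the
central 30 % of the *readout time* and 0.6x over the remainder, joined by a
cosine taper spanning 5 % of the readout so the gradient waveform stays
smooth. "Central 30 %" is interpreted in readout time (equivalently sample
count), not k-radius; this is configurable (`center_fraction`,
`taper_fraction`).

The traversal is integrated time-optimally: speed along the curve is
limited by `gamma*g_max` and by the curvature-dependent slew bound
`sqrt(gamma*s_max / kappa)`, with the tangential acceleration filling
whatever slew budget the centripetal term leaves (a 1 % safety factor keeps
the discretized waveform inside the limits). The arm pitch is the free
parameter: it is opened — radially faster, fewer turns — exactly as far as
the gradients force in order to reach `k_max = 1/(2*resolution)` inside
the readout window, but never tighter than the density prescription
itself, so relaxing the hardware limits shortens the readout instead of
producing an absurdly dense spiral. The pitch fit corresponds to a
(real-valued) full-set count `n_design` (~13.5 arms for the default
protocol).

Two interleaf counts must be distinguished:

* `n_design` — the rotated-copy count whose arm spacing realizes the
  designed pitch; the arm-spacing invariant `spacing = 1/(FOV*density)`
  holds for this count.
* `n_full` — the *fully-sampled interleaf count* used to quote the
  acceleration factor: the total Nyquist-weighted annular sample
  requirement of the density prescription, `FOV^2 * int d(r) 2*pi*r dr`
  (with `d(r)` mapped from readout time to k-radius through the designed
  trajectory), divided by the samples one interleaf delivers at the ADC
  dwell, rounded up. The dwell comes from the receiver bandwidth
  (1116 Hz/px at the rounded-up-even matrix 132 gives 6.79 µs, 783
  samples per 5.32 ms readout). For the default protocol the requirement
  is ~9.0e3 samples, so `n_full = ceil(11.5) = 12` and the quoted
  acceleration with two acquired interleaves per encoding is R = 6.

This sample-budget definition is the standard way variable-density spiral
protocols quote undersampling; a pure pitch-count reading would give
R ≈ 6.7–7 for the same trajectory.

Frames hold four readouts (FC, FE, FC at +180°, FE at +180°) at TR
11 ms — 44 ms temporal resolution — and successive frames rotate by the
golden angle 360(1 − 1/φ) = 137.50776405…°, carried at full precision.

Density compensation uses Voronoi cell areas on the sample cloud, closed
at the boundary by a guard ring of synthetic points just outside the
cloud; coincident samples (every rotated interleaf shares the k-space
origin) split their cell's weight equally. Degenerate clouds with fewer
than four distinct points fall back to equal weights summing to a nominal
cell area.

## Flow phantom

A transverse-chest digital phantom stands in for raw patient data: an
elliptical torso of static tissue (magnitude 1.0) containing an aorta-like
vessel (radius 14 mm, peak lumen velocity 115 cm/s) and a main pulmonary
artery-like vessel (16 mm, 82 cm/s), both brighter than tissue (1.4) as
inflowing blood is in gradient-echo imaging. Lumen velocity is parabolic
(Poiseuille) across the vessel. Each beat carries a single raised-cosine
(sin²) systolic pulse over 38 % of its RR interval on a near-zero
diastolic baseline; RR intervals are drawn as `rr_mean*(1 + rr_cv*z)`
with z standard normal (clipped at ±3σ), defaults 900 ms and 5 % matching
the beat-to-beat variability scale reported for free-breathing
acquisitions. Respiration multiplies the pulsatile component by
`1 + resp_amp*sin(2*pi*t/T_resp)` (defaults 6 %, 4 s — one full cycle per
scan). A bimodal-RR preset (alternating ~650/1150 ms) exercises the
beat-to-beat analysis under arrhythmia-like rhythm.

The phase-contrast signal model is the universal two-point convention:
`arg(FE) - arg(FC) = pi*v/venc` (VENC default 200 cm/s), wrapping
naturally through the complex exponential when |v| > VENC. The
flow-encoding bipolar is modeled as two back-to-back trapezoid lobes
(20 mT/m, 0.3 ms ramps) whose flat time solves the first-moment condition
`|m1| = g*(f+r)*(f+2r) = pi/(gamma*venc)`, falling back to slew-limited
triangular lobes when the moment is smaller than the shortest trapezoid.
Its lowest-order concomitant (Maxwell) field adds a quadratic phase
`gamma/(8*B0) * (x^2+y^2) * int Gz^2 dt` to FE at B0 = 0.55 T (about
0.3 rad at the FOV edge — non-negligible at mid-field), which downstream
correction must remove; the in-plane readout gradients are shared by FC
and FE and cancel in the difference.

Coils are smooth Gaussian-lobe sensitivities (8 by default) on a ring
around the torso with per-coil linear phase, seeded. Acquisition renders
one FC/FE image pair per 44 ms frame at the frame mid-time (intra-frame
motion is not modeled) and evaluates the forward NUFFT along each
scheduled rotated interleaf, adding seeded complex Gaussian noise.
`noise_sigma = 8` was calibrated once so the per-frame zero-filled
(density-compensated gridding) reconstruction has vessel-lumen magnitude
SNR ≈ 10, a low-field-like regime; the value is frozen.

Analytic ground truth integrates the prescribed velocity field exactly:
for the parabolic profile the flow rate is `Q(t) = v_c(t)/2 * pi*R^2`
(0.01 mL/s per cm/s·mm²), net flow is the fine-quadrature integral of Q
over each complete beat, and peak velocity is the continuous-time maximum
of the center velocity.

What the phantom does **not** emulate: relaxation and flip-angle effects,
slice profile, in-plane or through-plane vessel motion, off-resonance and
spiral blurring, eddy-current background phase, and intra-frame dynamics.
Passing the end-to-end tests therefore demonstrates correctness of the
sampling/reconstruction/quantification chain under the stated signal
model, not robustness to those physical confounds.

## NUFFT

Type-2 gridding NUFFT with a Kaiser–Bessel kernel (Beatty shape
parameter), oversampling 2 and width 6 by default (relative error vs. the
exact non-uniform DFT < 1e-5; width 8 reaches ~1e-7), implemented as a
sparse interpolation matrix over an FFT grid with exact adjoint. The
reconstruction uses single precision with oversampling 1.5 — the k-space
data carry noise orders of magnitude above the ~1e-4 kernel error.

## Reconstruction

Per velocity encoding (FC and FE are independent problems) the solver
minimizes

    J(u) = 1/2 ||F_Omega S u - d||^2 + lambda_s ||W_xy u||_1
                                     + lambda_t ||W_t u||_1

with `F_Omega` the per-frame NUFFT on that frame's two interleaves, `S`
the ESPIRiT coil maps, and `W_xy`, `W_t` energy-normalized non-decimated
(stationary) wavelet transforms — db2 over space (2 levels), Haar over
time (1 level; the 90-frame axis admits one undecimated level). The
PyWavelets `norm=True` transform is a Parseval tight frame, so the l1
proximal step is applied by analysis → magnitude soft-threshold →
synthesis (the standard tight-frame approximation).

The solver is a monotone FISTA: momentum steps whose candidates would
increase J are rejected and the momentum restarted, so the tracked
objective is non-increasing (to single-precision rounding); persistent
increases raise an explicit divergence error. The step size is
1/L with L from power iteration on representative frames (the per-frame
operators differ only by a global rotation). Because the model is linear,
the residual at the momentum point is an affine combination of cached
residuals, so one iteration costs a single forward plus a single adjoint
sweep.

Two choices matter for accuracy at R = 6 and were made after measuring
convergence on the noise-free phantom:

* **Warm start from the time-averaged image.** The golden-angle readouts
  pooled over all frames cover k-space completely, so the SENSE-combined
  gridding image of the pooled data (amplitude-calibrated against the
  per-frame data) starts the static background at essentially its
  converged value; iterations then only recover the dynamics. Without
  this, 60 iterations leave net flow ~19 % low.
* **Iteration budget.** `max_iters = 150` with relative-objective
  tolerance 1e-5. With the default regularization the solver converges in
  ~50–90 iterations; the cap only binds for weak regularization.

The weights `lambda_s = 80`, `lambda_t = 240` (units of the internally
scaled problem) were tuned on one seeded phantom dataset at the study
conditions and then frozen for all tests and seeds — net flow within ~2 %,
peak velocity within ~5 %, convergence ~3x faster than unregularized.

Coil maps come from ESPIRiT on the time-averaged flow-compensated image:
pooled FC readouts are gridded (Voronoi DCF), the central 24×24 Cartesian
block forms the calibration region, 6×6 kernels above 2 % of the leading
singular value are transformed to image space (normalization such that
the per-pixel operator has unit leading eigenvalue on the object), and
the leading eigenvector is kept where its eigenvalue exceeds 0.95,
phase-referenced to the strongest coil. All steps are deterministic.

## Velocimetry

Phase difference is the magnitude-robust conjugate product
`arg(FE * conj(FC))`; pixels with near-zero FC magnitude are set to zero
and flagged in a low-confidence mask. The Maxwell correction subtracts
the analytic concomitant-phase map computed from the encoding waveforms
(sampled piecewise-linear gradients are integrated segment-exactly:
`int (g0 + s t)^2 = h/3 (g0^2 + g0 g1 + g1^2)`); missing slice geometry
skips the correction with a logged warning. Velocity is `venc*dphi/pi`;
positive velocity means through-plane flow along the bipolar's slice
normal. Unwrapping is temporal-only: sweeping forward in time, each frame
shifts by the multiple of 2*VENC that minimizes its jump against the
previous frame — idempotent, and every change is an exact multiple of
2*VENC. Background (eddy-current) phase correction is deliberately not
implemented; the static-tissue bias is measured instead (< 1 cm/s on
noise-free data after Maxwell correction).

## Flow quantification

`q(t) = sum_mask v * pixel_area * 0.01` mL/s; net flow is the trapezoidal
integral over a beat, peak flow rate the beat maximum of q, peak velocity
the beat maximum of the ROI's single-pixel velocity maximum (a 95th-
percentile option exists; the single-pixel default is noisier and biased
slightly upward under noise, which partially offsets the smoothing-driven
underestimation). Beats are delimited by trigger times when available
(the phantom's own onsets, standing in for recorded ECG); otherwise by
systolic-upstroke detection on the Gaussian-smoothed curve (60 ms sigma,
onset at the 25 % amplitude crossing before each peak). Only complete
beats are kept. CV is the sample (n−1) standard deviation over the mean,
in percent. Qp/Qs is the ratio of beat-averaged MPA to aortic net flow.
ROIs for phantom pipelines are the known vessel discs; external data
accept mask images, and an Otsu-threshold helper on the temporal velocity
standard deviation is provided as a rough contouring aid, explicitly not
equivalent to clinical auto-contouring.

## Agreement statistics

Bland–Altman uses the exact 1.96 multiplier on the sample standard
deviation of the paired differences. The ICC is the two-way
random-effects, absolute-agreement, single-measures form ICC(2,1) —
appropriate for two fixed methods measured on the same subjects — with
the McGraw–Wong F-based 95 % interval (Satterthwaite degrees of freedom),
banded excellent (> 0.9) / good (0.6–0.9) / moderate (< 0.6); identical
pairs return ICC 1 with a collapsed interval, and constant data are
rejected. The paired t-test is two-sided with the convention p = 1 for
identical pairs. The blur metric is the no-reference re-blur construction
(strong low-pass, neighboring-gradient attenuation ratio, max over
horizontal/vertical), bounded in [0, 1]; a constant image is defined as 1.

## Problem sizes in the test suite

The acceptance-level end-to-end test runs the full study conditions —
132×132 matrix, 90 frames, 8 coils, R = 6, SNR ≈ 10 — once per session
(about 5 minutes). The noise-free static-bias check runs at 64×64 with
24 frames, where the property is scale-free; operator-level oracles run
at 16–32 pixels where dense-DFT references are exact and cheap.

## Known limitations

* The per-frame SENSE problem at R = 6 is underdetermined; accuracy rests
  on the spatiotemporal prior and the time-averaged warm start, and peak
  velocity converges slowest (sharpest feature). The residual peak-velocity
  underestimation (~3–7 %) matches the direction expected from temporal
  (44 ms) and spatial (2.3 mm) resolution limits.
* The spiral samples only the inscribed k-space disc; corner frequencies
  are a true null space, so sharp-edged objects can never be recovered
  exactly even fully sampled (the least-squares tests compare against a
  conjugate-gradient solve of the same normal equations for this reason).
* FC is modeled with zero net velocity-encoding gradient; real
  flow-compensated lobes contribute their own small concomitant terms.
* Temporal-only unwrapping cannot fix a series that is wrapped in every
  frame of a pixel.
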