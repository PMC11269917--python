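# Methods

This note documents the models, estimators and numerical choices behind
`csemri`, and what the synthetic experiments do and do not establish.

## Signal model

A voxel containing water and fat produces the multi-echo
chemical-shift-encoded (CSE) signal

    y(t) = (W + F * sum_m alpha_m exp(i omega_m t))
           * exp(i phi0) * exp((i 2 pi f0 - R2*) t)

with water/fat magnitudes `W, F >= 0`, a common initial phase `phi0`
(valid at low flip angles), B0 off-resonance `f0` (Hz), a single effective
transverse decay `R2*` (1/s) shared by both species, and a multi-peak fat
spectrum with relative amplitudes `alpha_m` (summing to 1) and angular
frequency offsets `omega_m = 2 pi * shift_ppm * 1e-6 * gamma * B0`.  The
proton-density fat fraction is PDFF = F/(W+F).

**Default fat spectrum.** Ten resonances of the standard triglyceride
proton model (chain length 17.4, 2.8 double bonds, 0.7 methylene-
interrupted double bonds), water referenced at 4.70 ppm, packaged as JSON
(`csemri/data/fat_spectrum_10peak.json`) and fully user-overridable.  The
dominant methylene peak sits at -3.40 ppm (-418 Hz at 2.89 T).

**In/out-of-phase delay.** The delay is 1/(2 |f_eff|) with `f_eff` the
amplitude-weighted mean fat frequency offset.  By default the mean runs
over the peaks spectrally *resolved* from water (|shift| >= 1 ppm): the
olefinic and glycerol resonances within ~0.6 ppm of water are
indistinguishable from it at clinical line widths and do not contribute to
the observable fat-water beat.  This convention yields 1.243 ms at 2.89 T;
`peaks="all"` (1.40 ms) and `peaks="dominant"` (1.20 ms) are available.

**Units.** Seconds, Hz, Tesla and radians internally; milliseconds and
degrees only at user boundaries (echo schemes, `phi0`).

## In-silico study design

The simulation grid assigns PDFF 0..100 % in 1 % steps along x, B0
off-resonance as a deterministic lattice -200..200 Hz in 4 Hz steps along
y, and independent noise repetitions along z, with `W + F = 1`,
`R2* = 50 1/s` and `phi0 = 30 deg` everywhere.  Echo schemes: 8-echo
monopolar (TE1/dTE = 1.16/1.96 ms) and 13-echo bipolar (1.12/1.07 ms),
both inside a 15 ms TR.

Volumes are normalized by 0.99 x the maximum first-echo magnitude (the
scale is recorded in the volume metadata, so results are invariant under
input rescaling).  Complex Gaussian noise is then added at a target SNR
defined against the **standard deviation of the complex noise**: each
real/imaginary component receives sigma = 1/(sqrt(2) * SNR), i.e.
E|eta|^2 = 1/SNR^2.  This is one of the two common MR conventions; it is
the one consistent with the reference accuracy figures this package
reproduces (the per-component sigma = 1/SNR convention places every error
metric a factor sqrt(2) higher).

**Accuracy metrics.** Bias and absolute error of PDFF and R2* are averaged
over the off-resonance and repetition axes to give per-true-PDFF profiles;
scalar summaries average over the whole grid, and the R2* headline number
is the maximum of the per-PDFF mean-absolute-error profile.  A voxel
counts as *swapped* when its estimate is closer to (100 - true) than to
the true fraction — note that near PDFF 50 % this definition flags
ordinary noise, so swap localization statements compare regions away from
the midpoint.  Metrics are computed on the signed PDFF estimate (below).

## Fat-water estimation

The estimator is a variable-projection (VARPRO) fit: for any candidate
pair (f0, R2*) the complex amplitudes enter linearly through the basis
{e(t), c(t) e(t)} with `e(t) = exp((i 2 pi f0 - R2*) t)` and `c(t)` the
fat phasor, so W and F are eliminated by linear least squares and only a
2-D nonlinear landscape remains.  The search has four stages:

1. **Coarse grid.**  f0 in [-600, 600] Hz step 8 Hz x R2* in [0, 300] 1/s
   step 50, using orthonormalized candidate bases stacked into one matrix
   (one GEMM per voxel block).  The basin width in f0 is ~1/(NTE * dTE),
   hundreds of Hz, so this grid always lands in the right basin and the
   spec-level resolution is recovered by refinement.  Two constraints act
   here:
   - a tiny relative penalty (4e-6 per Hz) on |f0| breaks the *exact*
     period-1/dTE degeneracy of species-pure voxels toward the smallest
     off-resonance (for the monopolar scheme the +-510 Hz aliases are
     otherwise populated by noise alone);
   - the per-candidate residual reduction is averaged over a 3^3 spatial
     neighborhood before the argmax.  Summing the profile likelihood over
     neighbors is the joint estimate of a locally shared field map with
     free per-voxel amplitudes — the "constrained" element that suppresses
     isolated fat-water swaps while leaving coherently ambiguous regions
     (true PDFF near 100 % at low SNR) to their fate.
2. **Refinement.**  Per-voxel parabolic coordinate descent on (f0, R2*),
   10 sweeps with halving steps, fully vectorized; R2* clamped to its
   bounds.
3. **R2* basin sweep.**  The neighborhood-aggregated coarse pick can leave
   individual voxels in a wrong decay basin; a per-voxel scan of the R2*
   grid at the refined f0, with re-refinement where a better basin exists,
   removes those.
4. **Field-map consistency iterations.**  Up to 3 passes: voxels whose f0
   deviates from the 3^3 median by more than 150 Hz are re-refined from
   the median and accepted when their residual is within a factor 2 of the
   unconstrained one.

**PDFF maps.**  Two estimates are produced. `pdff_map` uses magnitude
discrimination, 100 |F|/(|W|+|F|) with the complementary form on the fat-
dominant side, guaranteed in [0, 100]; its |W|, |F| are debiased for the
noncentral magnitude offset (subtracting twice the per-component CRLB
variance read off the median fit residual, with a second-order Jensen
refill).  `pdff_signed_map` projects W and F onto the common-phase axis
and takes the signed ratio 100 Re(F e^{-i phi})/|W+F|: noise at the 0 and
100 % boundaries stays symmetric instead of rectifying, which is the only
way a mean bias below 0.01 % at SNR 50 is attainable; accuracy statistics
therefore use the signed estimate, display maps the clipped one.

On the noiseless grid the fit recovers PDFF within 0.1 % and R2* within
0.5 1/s everywhere; at SNR 10 it is CRLB-efficient (verified by Monte
Carlo against the numerical Fisher information).  With the per-voxel
(unconstrained) configuration the classic failure mode appears exactly as
expected: fat-water swaps concentrate at true PDFF > 85 % for the 8-echo
monopolar scheme at SNR 10.

## Gradient chain and trajectory correction

Each gradient axis is modelled as an LTI system
`H(f) = exp(-i 2 pi f tau) * lowpass(f) * prod notches(f)` with an 8th-
order Butterworth magnitude roll-off (default cutoff 25 kHz) and
Lorentzian notches; defaults place mechanical resonances in the 3.3-4 kHz
band, deeper on x/y than z, with delays (1.0, 1.5, 2.5) us — the
qualitative signature of a real 3T gradient chain.  These parameter values
are scanner-class plausible, not measurements; every quantitative claim
about them is a recovery test of the package's own synthetic system.

The **two off-centered thin-slice measurement** integrates the actual
gradient into slice phase at +-5 mm (an offset keeping the per-sample
phase advance below pi up to 60 mT/m), takes the unwrapped phase
difference, and inverts the trapezoid integration exactly via the
recursion G[i+1] = 2 m[i] - G[i].  **GIRF estimation** is Tikhonov-
regularized deconvolution over a set of 12 slew-legal triangular blips of
distinct durations; the equivalent delay comes from a probe-energy-
weighted phase-slope fit, so poorly probed bands cannot corrupt it.
Round trip (measure on triangles, predict the multi-echo readout) is
accurate to ~0.03 % RMS in-band.

**Waveform prediction** multiplies in the frequency domain after zero-
padding to at least twice the waveform length; **trajectory integration**
is trapezoidal, in grid-point units (1/FOV).  Echo-parity analysis
projects the actual-vs-nominal displacement on the first echo's readout
direction, so a residual timing error splits even and odd echoes with
opposite signs; an optional first-echo timing calibration reproduces the
behavior of sequences that null the first-echo error (pure delays are then
fully compensated, richer distortions leave an even-echo residual).

## Phyllotaxis sampling and readout design

Spokes lie on a hemispheric spiral phyllotaxis, theta_n =
(pi/2) sqrt(n/N) with golden-angle azimuth increments, dealt round-robin
into segments so each segment spans the polar range, and a superior-
inferior (+z) spoke is prepended to every segment (3078 segments x 13 TRs
= 40014 spokes).  The readout designer builds slew- and amplitude-legal
trapezoid trains on a 10 us raster — alternating polarity for bipolar,
flyback rewinders for monopolar — with a prephaser sized so each echo's
k-space-origin crossing lands on the scheme's echo times within one raster
step.  Default protocol: (220 mm)^3 FOV, matrix 147, 1510 Hz/px, 60 mT/m,
200 T/m/s.

## Motion-resolved reconstruction (desk scale)

Self-gating reduces the SI projection stack by PCA and band-passes the
leading component time courses into respiratory (0.05-0.5 Hz) and cardiac
(0.5-3 Hz) channels at the ~5 Hz segment rate.  Spokes are binned into 4
equal-count respiratory amplitude bins and 100 ms cardiac windows from
detected triggers (spokes beyond the last full window of a beat join the
final bin).  Coil data are compressed by SVD with a 2 % singular-value
threshold.

Each bin is reconstructed by Kaiser-Bessel gridding NUFFT (2x
oversampling, width-4 kernel, Beatty beta, validated to ~6e-4 against a
direct non-uniform DFT) with radial density compensation (|k| ramp in 2-D,
|k|^2 in 3-D; the central cell gets its proper delta/4 effective radius so
the DC samples of every spoke are not overweighted; a Jacobian |dk/ds|
factor handles distorted spokes).  The compressed-sensing problem

    min_x 0.5 sum_b ||A_b x_b - y_b||^2 + lam_s TV_xy + lam_c TV_card + lam_r TV_resp

uses anisotropic TV (l1 of forward differences), cyclic along the cardiac
dimension, clamped elsewhere, and is solved by ADMM (default
lam_s/lam_c/lam_r = 0.0015/0.0075/0.005, rho = 0.06, 10 iterations, inner
CG warm-started).  Data are normalized so the gridding image has unit peak
magnitude, keeping the TV weights scale-meaningful.  The demo problem is
2-D radial + cardiac + respiratory at a 32-48 pixel matrix; the full-scale
problem (147^3, 13 echoes, ~32 bins) runs the same code path but is far
outside interactive compute budgets.

**Trajectory-artifact experiment.**  A water-only analytic disk phantom
(closed-form k-space, so the reconstruction grid never enters the data
simulation) is acquired on a two-echo bipolar radial readout through a
distorting chain; echo images are gridded assuming the nominal vs the
GIRF-predicted trajectory and compared by the normalized echo-2/echo-1
magnitude difference.  The demo chain uses a 5 us common delay — the same
shift-to-resolution severity at matrix 48 as ~1-point even-echo shifts at
full resolution — and the waveform raster is refined to 2 us so the
chain's lowpass genuinely smooths gradient corners before the fractional
delay (on a coarse raster an ideal fractional-sample delay of a sharp
trapezoid manufactures interpolation ringing that contaminates even the
corrected reconstruction).  Corrected gridding is consistently ~4-10x more
echo-consistent than nominal.

## What the synthetic experiments do not show

- The gradient-chain parameters are plausible defaults, not measurements;
  agreement of delay/notch recoveries says nothing about any specific
  scanner.
- The in-silico grid has a perfectly smooth field map and a single shared
  R2*; the field-map constraint is accordingly more effective there than
  it can be in vivo (air-tissue interfaces, lungs).
- The dynamic phantom is piecewise-constant and strictly periodic, ideal
  for TV regularization and spectral gating; real motion is neither.
- No coil-sensitivity estimation, no eddy-current/concomitant-field
  modelling, no scanner raw data handling.

## Problem sizes

The packaged study runs the full 101 x 101 PDFF x off-resonance grid with
the repetition axis scaled to 4 repetitions x 3 seeds (12 effective
repetitions, ~120k voxel fits per condition); the accuracy metrics are
means over >= 40k cells per repetition and are stable at this scale.  The
reconstruction demos use 32-48 pixel matrices with undersampling factors
matching the full-scale protocol.
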