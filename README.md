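# csemri

Free-running chemical-shift-encoded (CSE) cardiac MRI toolkit: multi-peak
fat-water signal simulation, IDEAL-type PDFF/R2*/B0 mapping, gradient
impulse response function (GIRF) trajectory correction, 3D radial
spiral-phyllotaxis sampling, and motion-resolved compressed-sensing
reconstruction — built for quantitative-MRI researchers who want to study,
end to end and on a desk, why fast bipolar multi-echo readouts need
trajectory correction before they yield accurate fat-fraction maps.

## The problem

Proton-density fat fraction, PDFF = F/(W+F), is a tissue-composition
biomarker (epicardial fat, fatty infiltration, marrow).  Mapping it in the
beating, breathing heart at 3T requires many echoes inside a short TR,
which pushes toward bipolar readout gradients with echo spacing below the
fat-water in/out-of-phase delay (~1.24 ms at 2.89 T) — spacing the slower
monopolar scheme cannot reach (1.96 ms), at the price of odd/even-echo
trajectory inconsistencies from gradient-chain imperfections.  This
package implements the whole computational chain:

- the CSE signal model
  `y(t) = (W + F Σ α_m e^{iω_m t}) e^{iφ0} e^{(i2πf0 − R2*)t} + η(t)`
  with a packaged 10-peak subcutaneous triglyceride spectrum;
- an in-silico accuracy study over a PDFF × off-resonance × repetition
  grid at SNR 10 and 50 for the 8-echo monopolar and 13-echo bipolar
  schemes;
- a variable-projection (VARPRO) fat-water estimator with joint B0/R2*
  search and a spatial field-map constraint (PDFF, R2*, B0 and residual
  maps);
- per-axis LTI gradient-chain modelling, simulated thin-slice GIRF
  measurement, regularized deconvolution, waveform prediction and k-space
  trajectory integration with echo-parity shift analysis;
- segmented spiral-phyllotaxis direction sets (3078 segments × 13 TRs =
  40014 spokes with a superior-inferior spoke per segment) and
  hardware-legal monopolar/bipolar readout gradient design;
- self-gating from SI projections, respiratory/cardiac binning, SVD coil
  compression, Kaiser-Bessel gridding NUFFT and ADMM total-variation
  compressed sensing across spatial/cardiac/respiratory dimensions.

See `docs/methods.md` for models, conventions and numerical choices.

## Worked example

Simulate the bipolar in-silico study at SNR 10 (2 repetitions for speed),
fit it, and read the accuracy report:

```bash
csemri simulate --out vol.h5 --scheme bipolar3T --snr 10 --seed 1 --reps 2
csemri fit vol.h5 --out-prefix maps
csemri report maps_report.json
```

which prints (abridged):

```json
{
  "n_voxels": 20402,
  "mean_bias_pdff": -0.0011,
  "mean_abs_err_pdff": 2.1987,
  "mean_bias_r2s": -0.0694,
  "max_abs_err_r2s": 12.0417,
  "swap_fraction_total": 0.0145
}
```

The 13-echo bipolar scheme at SNR 10 recovers PDFF with ~2.2 % mean
absolute error, essentially zero bias, and R2* errors peaking in the
mid-PDFF range — the accuracy regime that makes bipolar acquisition worth
the trajectory trouble.  The same library calls are available in Python
(`generate_silico_volume`, `fit_volume`, `accuracy_report`, ...).

The trajectory side of the story:

```bash
csemri girf --out-prefix girf --axis z     # estimated delay: 2.500 us
csemri recon-demo --out rd.json            # nominal 0.0137 vs corrected 0.0015
```

the recon demo acquires a water-only phantom through a distorting gradient
chain and shows the even/odd-echo image inconsistency dropping ~9x when
the GIRF-predicted trajectory replaces the nominal one at gridding.

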