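# conetraj

Design and evaluation of parametric **3D cone k-space trajectories** for
dynamic non-Cartesian MRI — in particular for combined arterial-spin-labeling
(ASL) angiography and perfusion imaging, where one continuously acquired
dataset is binned twice: at high spatiotemporal resolution with the full
k-space (angiography) and at low spatiotemporal resolution with only the
central k-space (perfusion).

The package is a pure-Python library (numpy/scipy stack) for MRI pulse
sequence and reconstruction researchers. It covers the whole desk-side
workflow: trajectory geometry → hardware-constrained gradient waveforms →
golden-ratio shot scheduling → synthetic phantom acquisition → trajectory
quality metrics → adjoint and locally-low-rank reconstruction.

## The model

A single readout ("shot") follows a two-stage cone in k-space,

```
k(α) = ẑ·k_max·cosθ·α + (x̂·cos(Aα) + ŷ·sin(Aα)) · r(α),   0 < α ≤ 1

r(α) = m^(n−1)·k_max·sinθ·α    for α ≤ m     (fixed-angle cone)
r(α) = k_max·sinθ·α^n          for α > m     (cone angle opens with radius)
```

with cone half-angle θ, stage separation m, curvature power n, and twist
scaling A chosen so that the time-optimal traversal under gradient amplitude
and slew limits (G_max, S_max) lasts exactly the requested readout time. The
two branches join continuously at α = m; the endpoint always sits at radius
k_max at angle θ from the axis. Shots are rotated over the sphere by the 3D
golden means (φ₂ the real root of x³ + x = 1, φ₁ = φ₂²), incrementing the
golden index first across repeats and then across time, so any contiguous
group of shots — any temporal binning chosen after the scan — covers the
sphere near-uniformly. An extra random spin about each cone axis decorrelates
the azimuthal sampling.

Sampling patterns are scored by the PSF full width at half maximum (FWHM),
the pseudo-replica effective SNR (noise replicas reconstructed through the
density-compensated adjoint NUFFT, compensated by the FWHM volume), and the
signal-to-aliasing power ratio (SAPR). Dynamic series are reconstructed
either by the density-compensated adjoint or by locally-low-rank (LLR)
regularized least squares,

```
x̂ = argmin_x ‖PFCx − y‖² + λ·Σᵢ ‖Rᵢx‖_*
```

solved by proximal gradient with patch-wise singular-value thresholding
(default λ = 0.1 on unit-peak-normalized data, 5×5×5 patches).

## Worked example

```bash
python examples/01_design_cone.py
```

prints (numbers produced by the code):

```
nominal resolution : 1.13 mm (k_max = 0.4425 1/mm)
stage-1 cone angle : 23.41 deg (opens to 60 deg at the trajectory end)
twist scaling A    : 42.41 rad (6.8 azimuthal turns over the readout)
readout duration   : 10.02 ms (target 10 ms)
max |g|            : 11.62 mT/m  (limit 11.64)
max slew           : 61.42 T/m/s (limit 61.54)
ADC samples        : 5013 at 2 us dwell, endpoint |k| = 0.4425 1/mm
```

The stage-1 segment is a tight 23.4° cone that clears the k-space center
quickly; beyond the separation point the cone opens to 60°, spending the
twist budget on peripheral k-space. The waveform rides the slew limit in the
twisted center and the amplitude limit outside, and both stay inside the
protocol limits, so the designed readout is playable on the scanner.

Other examples: `02_schedule_and_binning.py` (golden-ratio scheduling, the
12-frame angiographic / 6-frame perfusion dual binning of a 2116.8 ms
readout train), `03_psf_metrics.py` (FWHM / effective SNR / SAPR of one
binned frame), `04_simulate_and_reconstruct.py` (multi-coil dynamic
simulation, adjoint vs LLR), `05_parameter_sweep.py` (the (θ, m, n, readout)
design-grid sweep to CSV).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch: the number of angiographic frames obtained by
binning the full 48-repeat, 2116.8 ms readout train at a 176.4 ms window
(t3), and the maximum gradient amplitude (t6) and maximum vector slew rate
(t7) over the designed in vivo cone readout (θ = 60°, m = 0.5, n = 3, 10 ms,
1.13 mm isotropic), which must respect the protocol limits of 11.64 mT/m and
61.54 T/m/s. Results are written as JSON to `--out`.

See `docs/methods.md` for the numerical methods, defaults and limitations.
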