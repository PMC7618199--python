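# Methods

This note documents the models, numerical choices and limitations of
`conetraj`, in the order of the processing chain.

## Cone geometry

The two-stage cone is purely geometric in the curve parameter α ∈ (0, 1];
timing is delegated entirely to the waveform solver. The stage-1 transverse
law `m^(n−1)·k_max·sinθ·α` and stage-2 law `k_max·sinθ·α^n` are the unique
pair of the form (c·α, k_max·sinθ·α^n) that is continuous at α = m — the
stage-1 cone is a fixed-angle cone of half-angle `arctan(m^(n−1)·tanθ)` that
opens into the power-law cone at the separation point. Setting m = 0 gives
the single-stage (pure power-law) design; θ = 0 collapses everything to a
radial spoke, which is used as a cross-module oracle throughout the tests.
Angles are degrees at every public interface, radians internally.

## Time-optimal gradient waveforms

The solver re-parameterizes the curve by arc length (cubic-spline fit against
chord length; curvature from spline derivatives, κ = |k′×k″|/|k′|³) and
integrates the speed profile forward and backward:

* pointwise cap: v ≤ γG_max and v² ≤ γS_max/κ (centripetal limit);
* tangential acceleration bound: a ≤ sqrt((γS_max)² − κ²v⁴);
* v(0) = 0; the end velocity defaults to **zero** (the closed-form oracle for
  a straight spoke is then the triangular ramp 2·sqrt(k_max/(γS_max))); a
  "free" end-velocity option exists for readouts followed by a rewinder that
  absorbs the ramp-down.

Time along the path uses Δt = 2Δs/(vᵢ+vᵢ₊₁), exact for piecewise-constant
tangential acceleration, and the same quadratic model inverts t(s) at the
raster times, which keeps the rasterized start/end ramps slew-accurate. A
design derating of 0.2% (`safety = 0.998`) on both limits absorbs the
residual discretization overshoot so the discrete waveform (piecewise-
constant gradient at a 10 µs raster) honors the full limits; the default
arc grid is 20 000 points, at which the in vivo design's max slew sits ~0.2%
below the limit. γ defaults to the proton value 42.5764 kHz/mT.

The twist scaling A is solved by bracketing + bisection on the (non-
decreasing) duration-vs-A map to 0.5% relative duration tolerance.

## Shot scheduling

The 3D golden means are computed at runtime: φ₂ is the real root of
x³ + x = 1 (Cardano), φ₁ = φ₂². Axis i is z = 2·frac(i·φ₁) − 1,
azimuth 2π·frac(i·φ₂) — the full sphere, since each cone only covers a cap
around its axis. Shot (repeat r, TR t) gets golden index i = t·n_repeats + r
(repeat fastest), so grouping shots across repeats at any temporal window
yields a contiguous golden subsequence. The random spin about each cone axis
is uniform on [0, 2π), drawn once per shot from a seeded generator in
golden-index order (the schedule is a pure function of the seed). The
alternative index order (i = r·n_tr + t) is available as an option.

Binning: frames collect shots whose TR start time falls in the window;
k-radius restriction keeps samples with |k| ≤ f·k_max (rotation-invariant, so
it is applied to the base samples). The "half the shots" angiographic
convention has two readings: in the simulation convention, the angiographic
window is half the perfusion window so an angiographic frame naturally
contains half the shots of a perfusion frame (this is the default: all
repeats, shorter window); a separate `half_shots` option additionally keeps
only the first half of the repeats per window (preserving golden contiguity),
matching the stricter reading. Both are exercised in tests.

## NUFFT

No NUFFT library is assumed: the package implements a Kaiser–Bessel gridding
NUFFT (oversampling 2.0, kernel width 5, Beatty shape parameter). The
apodization correction is the kernel's continuous Fourier transform evaluated
by quadrature, keeping kernel and correction consistent by construction.
Forward accuracy against a brute-force DFT is ~1e−4 relative at the defaults
(width 8 reaches ~1e−7 and is used where a test needs 1e−6); the adjoint is
the exact algebraic adjoint of the implemented forward (same interpolation
matrix, conjugate transforms), so ⟨Fx, y⟩ = ⟨x, F†y⟩ holds to machine
precision — the property the iterative reconstruction requires.

## Density compensation, PSF, FWHM

Density compensation is the iterative gridding-density (Pipe–Menon) fixed
point w ← w/(PPᴴw), 20 iterations (trajectory-agnostic; the method is not
specified by the protocol, so iteration count is fixed and logged on
request). Weights are normalized so the weighted adjoint of all-ones data has
unit PSF peak, which makes the fully sampled Cartesian case quantitatively
the inverse DFT. Near the sampling boundary the weights deviate from the
interior analytic density (checked on 3D radial shells in the tests).

The PSF is the weighted adjoint of unit data, peak-normalized, optionally
after a radial Hann window w(|k|) = 0.5·(1 + cos(π|k|/k_max)). FWHM is
measured per cardinal axis through the peak after 8× Fourier zero-padding
interpolation, with linear interpolation of the two half-maximum crossings —
deterministic sub-voxel precision, validated to 1% against the Gaussian
closed form 2.3548σ.

## Pseudo-replica effective SNR and SAPR

Replica reconstructions add complex Gaussian noise (σ per complex sample) to
the data and pass it through the weighted adjoint; the per-voxel standard
deviation of the complex reconstructions across replicas, averaged over the
foreground mask, is the noise level (foreground-averaged rather than
global-averaged — the choice matters little for the scaling behavior and is
flagged here). Signal is the mean noiseless foreground magnitude. The SNR is
divided by the product of the three axis FWHMs in voxels (a voxel-volume
proxy), so intrinsic smoothing cannot masquerade as SNR. Defaults: 64
replicas; σ is specified by the caller, conventionally relative to the peak
data magnitude (the underlying noise level of the reference experiments is
not stated anywhere, so all outputs carry the σ used). SAPR is mean |I|² over
the foreground divided by mean |I|² over the background, +inf (with a
warning) when the background is exactly zero.

## Phantoms and forward model

The generators are pure functions of (parameters, seed). The vessel phantom
(smooth spline-centerline tubes, radii tapering 3→1 voxels scaled to the
matrix, foreground < 5%) stands in for a high-quality angiogram: it has the
right sparsity and tubular geometry but no flow, no background tissue and no
coil-dependent intensity. The perfusion phantom (nested smoothed ellipsoids
with a gray/white-like 1.0/0.4 contrast, raised-cosine band limit well inside
half-Nyquist) stands in for a perfusion map so that a one-third-k-radius
reconstruction is meaningful. The comb phantom provides bar patterns for
resolution scoring. Coil maps are broad complex Gaussians on a ring (default
8 coils, matching a 32→8 channel compression) with smooth phase. A green test
therefore establishes correct sampling/reconstruction behavior on objects
with these statistics — not in vivo image quality, motion robustness or
off-resonance behavior.

The forward model is the sensitivity-weighted forward NUFFT plus complex
Gaussian noise; it contains no relaxation or off-resonance by default. An
optional mono-exponential decay hook (`t2star_ms`) exists for
readout-duration experiments.

## Reconstruction

Adjoint mode: per frame, optional Hann windowing, density-weighted adjoint
per coil, conjugate-sensitivity combination normalized by Σ|C|². The Hann
window is applied in both adjoint and LLR modes when requested (the protocol
statement is reconstruction-wide; it is toggleable).

LLR mode: proximal gradient (FISTA acceleration with monotone restart;
backtracking on the quadratic majorizer). The step defaults to 1/(1.05·L)
with L from 12 power iterations on AᴴA. Patches are non-overlapping cubes
(default 5³) with a seeded random cyclic shift; by default the shift is
re-drawn each outer iteration (cycle spinning, suppresses blocking), in which
case the logged objective is evaluated on the current tiling and may wobble;
with `cycle_spin=False` the tiling is fixed and the objective is provably
non-increasing — the monotonicity tests use that configuration, and a
persistent increase raises a solver error. λ is interpreted on data
normalized so the plain adjoint image has unit peak, making λ = 0.1
transferable across data scales. Stopping: 200 iterations or relative
objective change < 1e−6. With λ = 0 the iteration reduces to accelerated
gradient descent from zero and converges to the minimum-norm least-squares
solution, cross-checked against conjugate gradient on the normal equations.

Coil compression is an SVD basis fitted on the data; sensitivities map into
the compressed basis with the conjugate mixing matrix, which leaves the
adjoint reconstruction invariant when no energy is discarded.

The dual reconstruction reconstructs angiography (full k, short window) and
perfusion (central k, long window) from the same raw data; the perfusion grid
is coarsened by the k-radius fraction (grid size bumped, if needed, so its
Nyquist still covers the retained radius).

## Known limitations

* No ASL signal physics: labeling efficiency, blood T1, flip-angle
  attenuation are out of scope; the flip-angle schedule is carried as data.
* No eddy currents, gradient impulse response, or off-resonance in the
  forward model; the conservative gradient limits are the only concession to
  gradient imperfections.
* The two-stage vs single-stage FWHM ordering is a sub-percent effect at
  desk scale and sensitive to the density-compensation method; see the
  regression test for the configuration in which it is asserted.
* Sensitivity maps are taken as known (simulated); estimation from data is
  not implemented.
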