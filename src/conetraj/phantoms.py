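"""Synthetic digital phantoms and the multi-coil k-space forward model.

Three phantom families stand in for the reference objects used to score a
trajectory:

* ``vessel`` — sparse, bright, tube-like structures following smooth random
  centerlines (the kind of object a high-quality angiogram contains);
* ``perfusion`` — smooth, band-limited compartments with distinct
  gray/white-matter-like intensities (a perfusion-weighted signal);
* ``comb`` — bar patterns at prescribed spacings for resolution scoring.

All generators are pure functions of (parameters, seed).  The forward model
is the sensitivity-weighted forward NUFFT plus complex Gaussian noise; no
relaxation or off-resonance is applied by default (an optional
mono-exponential decay hook exists for readout-duration experiments).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter

from .nufft import NUFFT3


class PhantomGenerationError(RuntimeError):
    """Could not realize a phantom with the requested geometry."""


@dataclass(frozen=True)
class DigitalPhantom:
    """A 3D intensity grid with voxel size, support mask and provenance."""

    volume: np.ndarray
    voxel_size: float
    foreground_mask: np.ndarray
    kind: str
    seed: int | None = None

    @property
    def matrix(self) -> tuple[int, int, int]:
        return tuple(self.volume.shape)


@dataclass(frozen=True)
class CoilModel:
    """Smooth complex coil sensitivity maps, (n_coils, N, N, N)."""

    sensitivities: np.ndarray

    @property
    def n_coils(self) -> int:
        return self.sensitivities.shape[0]

    def rss(self) -> np.ndarray:
        return np.sqrt(np.sum(np.abs(self.sensitivities) ** 2, axis=0))


def _grid_mm(matrix: int, voxel_size: float) -> np.ndarray:
    idx = np.arange(matrix) - matrix // 2
    return idx * voxel_size


def make_vessel_phantom(
    matrix: int = 64,
    voxel_size: float = 1.0,
    n_vessels: int = 8,
    seed: int = 0,
    max_retries: int = 20,
) -> DigitalPhantom:
    """Sparse vessel-like phantom: smooth random 3D tubes with tapering radii.

    Each vessel follows a cubic-spline centerline through random control
    points; its radius tapers from ~3 to ~1 voxels along the path.  The
    foreground (non-zero) fraction stays below 5% for the default settings.
    """
    if matrix < 32:
        raise ValueError("matrix must be >= 32 for a meaningful vessel phantom")
    rng = np.random.default_rng(seed)
    vol = np.zeros((matrix, matrix, matrix))
    if n_vessels == 0:
        return DigitalPhantom(vol, voxel_size, vol != 0, "vessel", seed)

    coords = np.indices((matrix, matrix, matrix)).astype(float)
    base_scale = min(1.0, matrix / 64.0)
    for attempt in range(max_retries):
        vol[:] = 0.0
        shrink = base_scale * 0.8 ** attempt
        for _ in range(n_vessels):
            n_ctrl = rng.integers(4, 7)
            ctrl = rng.uniform(0.12 * matrix, 0.88 * matrix, size=(n_ctrl, 3))
            t = np.linspace(0.0, 1.0, n_ctrl)
            spline = CubicSpline(t, ctrl, axis=0)
            tt = np.linspace(0.0, 1.0, 12 * matrix)
            center = spline(tt)
            inside = np.all((center >= 1) & (center <= matrix - 2), axis=1)
            center = center[inside]
            if center.shape[0] < 10:
                continue
            radius = np.linspace(3.0, 1.0, center.shape[0]) * rng.uniform(0.6, 1.0) * shrink
            intensity = rng.uniform(0.7, 1.0)
            for c, r in zip(center[::3], radius[::3]):
                lo = np.maximum(np.floor(c - r - 1).astype(int), 0)
                hi = np.minimum(np.ceil(c + r + 2).astype(int), matrix)
                box = coords[:, lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
                d2 = sum((box[d] - c[d]) ** 2 for d in range(3))
                vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = np.maximum(
                    vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]],
                    intensity * (d2 <= r * r),
                )
        frac = np.count_nonzero(vol) / vol.size
        if 0.0 < frac < 0.05:
            return DigitalPhantom(vol, voxel_size, vol != 0, "vessel", seed)
    raise PhantomGenerationError(
        f"could not realize a sparse vessel phantom in {max_retries} attempts"
    )


def make_perfusion_phantom(matrix: int = 64, voxel_size: float = 1.0, seed: int = 0) -> DigitalPhantom:
    """Smooth compartment phantom with gray/white-like intensity contrast.

    Two nested ellipsoids (outer "gray matter"-like rim brighter than the
    inner "white matter"-like core) are smoothed and band-limited so that the
    spectral energy above half the grid Nyquist is negligible — a coarse
    (one-third k-radius) reconstruction of it is therefore meaningful.
    """
    rng = np.random.default_rng(seed)
    idx = np.arange(matrix) - matrix // 2
    X, Y, Z = np.meshgrid(idx, idx, idx, indexing="ij")

    def ellipsoid(semi, center, tilt):
        x = (X - center[0]) / semi[0]
        y = (Y - center[1]) / semi[1]
        z = (Z - center[2]) / semi[2]
        return (x * x + y * y + z * z + tilt * x * y) <= 1.0

    outer_semi = np.array([0.38, 0.32, 0.34]) * matrix * rng.uniform(0.95, 1.05, 3)
    inner_semi = outer_semi * rng.uniform(0.55, 0.65, 3)
    center = rng.uniform(-0.03, 0.03, 3) * matrix
    outer = ellipsoid(outer_semi, center, rng.uniform(-0.1, 0.1))
    inner = ellipsoid(inner_semi, center, rng.uniform(-0.1, 0.1))

    vol = np.zeros((matrix, matrix, matrix))
    vol[outer] = 1.0    # gray-matter-like perfusion level
    vol[inner] = 0.4    # white-matter-like (lower) perfusion

    vol = gaussian_filter(vol, sigma=0.05 * matrix)
    # hard band limit with a raised-cosine rolloff well inside Nyquist/2
    spec = np.fft.fftshift(np.fft.fftn(vol))
    f = np.sqrt(X ** 2 + Y ** 2 + Z ** 2) / matrix  # cycles per voxel
    cutoff, roll = 0.12, 0.06
    taper = np.clip((cutoff + roll - f) / roll, 0.0, 1.0)
    taper = 0.5 - 0.5 * np.cos(np.pi * taper)
    vol = np.fft.ifftn(np.fft.ifftshift(spec * taper)).real
    vol = np.maximum(vol, 0.0)
    mask = vol > 0.05 * vol.max()
    return DigitalPhantom(vol, voxel_size, mask, "perfusion", seed)


def make_comb_phantom(matrix: int = 64, voxel_size: float = 1.0,
                      bar_spacings: tuple[float, ...] = (2.0, 4.0, 8.0)) -> DigitalPhantom:
    """Resolution comb: bar patterns at the requested spacings (mm).

    Each requested spacing gets a slab of bars alternating along the first
    axis with period ``spacing`` (bar width = spacing/2); an empty spacing
    list yields a uniform phantom.  Bar modulation depth after reconstruction
    scores achievable resolution.
    """
    vol = np.ones((matrix, matrix, matrix))
    if len(bar_spacings) == 0:
        return DigitalPhantom(vol, voxel_size, vol != 0, "comb", None)
    vol[:] = 0.0
    x_mm = _grid_mm(matrix, voxel_size)
    n_blocks = len(bar_spacings)
    block = matrix // n_blocks
    margin = max(2, matrix // 16)
    for b, spacing in enumerate(bar_spacings):
        bars = (np.mod(x_mm, spacing) < spacing / 2.0).astype(float)
        sl_y = slice(b * block + 1, min((b + 1) * block - 1, matrix))
        vol[margin:-margin, sl_y, margin:-margin] = bars[margin:-margin, None, None]
    return DigitalPhantom(vol, voxel_size, vol != 0, "comb", None)


def make_coil_model(matrix: int, n_coils: int = 8, seed: int = 0) -> CoilModel:
    """Smooth complex sensitivities: Gaussian lobes around the FOV + smooth phase.

    Coil centers sit on a circle just outside the volume; magnitudes are
    broad Gaussians (so the root-sum-of-squares is strictly positive
    everywhere) and phases vary linearly plus a mild quadratic term.
    """
    rng = np.random.default_rng(seed)
    idx = (np.arange(matrix) - matrix // 2) / matrix
    X, Y, Z = np.meshgrid(idx, idx, idx, indexing="ij")
    maps = np.empty((n_coils, matrix, matrix, matrix), dtype=complex)
    for c in range(n_coils):
        ang = 2.0 * np.pi * c / n_coils
        cx, cy = 0.6 * np.cos(ang), 0.6 * np.sin(ang)
        cz = 0.3 * np.sin(2 * ang) + rng.uniform(-0.05, 0.05)
        mag = np.exp(-((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2) / (2 * 0.45 ** 2))
        lin = rng.uniform(-2.0, 2.0, 3)
        phase = lin[0] * X + lin[1] * Y + lin[2] * Z + rng.uniform(-1, 1) * (X * Y)
        maps[c] = (0.2 + mag) * np.exp(1j * phase)
    return CoilModel(sensitivities=maps)


def simulate_acquisition(
    phantom: DigitalPhantom,
    coils: CoilModel,
    samples: np.ndarray,
    noise_sigma: float = 0.0,
    seed: int = 0,
    t2star_ms: float | None = None,
    sample_times_ms: np.ndarray | None = None,
    nuffts: NUFFT3 | None = None,
) -> np.ndarray:
    """Simulate per-coil k-space data along a trajectory.

    Forward NUFFT of each sensitivity-weighted phantom volume at the sample
    positions, plus complex Gaussian noise of std ``noise_sigma`` per complex
    sample.  Optional mono-exponential T2* decay weights samples by
    ``exp(-t/T2*)`` (disabled by default).  Linear in the phantom.

    Returns
    -------
    data : (n_coils, S) complex array
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    nyq = 1.0 / (2.0 * phantom.voxel_size)
    if np.max(np.abs(samples)) > nyq * (1 + 1e-9):
        raise ValueError("sample coordinates exceed the phantom grid Nyquist")
    op = nuffts if nuffts is not None else NUFFT3(samples, phantom.matrix, phantom.voxel_size)
    rng = np.random.default_rng(seed)
    decay = 1.0
    if t2star_ms is not None:
        if sample_times_ms is None:
            raise ValueError("sample_times_ms required when t2star_ms is set")
        decay = np.exp(-np.asarray(sample_times_ms) / t2star_ms)
    data = np.empty((coils.n_coils, op.n_samples), dtype=complex)
    for c in range(coils.n_coils):
        data[c] = op.forward(coils.sensitivities[c] * phantom.volume) * decay
    if noise_sigma > 0:
        data += noise_sigma * (rng.standard_normal(data.shape)
                               + 1j * rng.standard_normal(data.shape)) / np.sqrt(2.0)
    return data


def make_dynamic_series(
    phantom_pair: tuple[DigitalPhantom, DigitalPhantom | None],
    n_frames: int,
    inflow_profile: np.ndarray | None = None,
    perfusion_profile: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Dynamic volume series: vessel inflow-then-decay, late perfusion rise.

    ``phantom_pair = (vessel, perfusion_or_None)``.  The vessel volume is
    scaled per frame by ``inflow_profile`` (default: a monotone rise peaking
    at ~40% of the series then exponential decay); the perfusion volume, if
    given, rises smoothly in the late frames.  With a constant profile and no
    perfusion phantom all frames are identical.

    Returns
    -------
    series : (n_frames, N, N, N) array
    """
    vessel, perf = phantom_pair
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if inflow_profile is None:
        t = np.arange(n_frames, dtype=float)
        t_peak = max(1.0, 0.4 * (n_frames - 1))
        inflow_profile = np.where(
            t <= t_peak, t / t_peak, np.exp(-(t - t_peak) / max(1.0, 0.35 * n_frames))
        )
        if n_frames == 1:
            inflow_profile = np.ones(1)
    inflow_profile = np.asarray(inflow_profile, dtype=float)
    if inflow_profile.shape[0] != n_frames:
        raise ValueError("inflow_profile length must equal n_frames")

    series = inflow_profile[:, None, None, None] * vessel.volume[None]
    if perf is not None:
        if perfusion_profile is None:
            t = np.arange(n_frames, dtype=float)
            perfusion_profile = 1.0 / (1.0 + np.exp(-(t - 0.7 * (n_frames - 1)) / max(0.5, 0.1 * n_frames)))
        perfusion_profile = np.asarray(perfusion_profile, dtype=float)
        if perfusion_profile.shape[0] != n_frames:
            raise ValueError("perfusion_profile length must equal n_frames")
        series = series + perfusion_profile[:, None, None, None] * perf.volume[None]
    return series


def phantom_to_nifti(phantom: DigitalPhantom, path) -> None:
    """Write the phantom as NIfTI with the voxel size in the header."""
    import nibabel as nib

    affine = np.diag([phantom.voxel_size] * 3 + [1.0])
    nib.save(nib.Nifti1Image(phantom.volume.astype(np.float32), affine), str(path))


def raw_data_to_hdf5(data: np.ndarray, path) -> None:
    """Write per-coil raw k-space data as /data/coil_k (C x S complex)."""
    import h5py

    with h5py.File(path, "a") as f:
        if "data/coil_k" in f:
            del f["data/coil_k"]
        f.create_dataset("data/coil_k", data=np.asarray(data, dtype=complex))
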